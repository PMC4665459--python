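# bayesdta: verification
# five-category mammography with partial verification; 1509 subjects
category,verified_diseased,verified_nondiseased,unverified
1,72,308,92
2,54,127,66
3,121,78,76
4,145,33,10
5,245,77,5
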