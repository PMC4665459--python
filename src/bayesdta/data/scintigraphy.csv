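# bayesdta: verification
# hepatic scintigraphy; category 1 = Y=0 (negative), category 2 = Y=1
category,verified_diseased,verified_nondiseased,unverified
1,31,48,117
2,298,26,150
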