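# bayesdta: ordinal
# categories: 1 normal .. 5 malignant; 30 cancer and 30 cancer-free women
category,diseased,nondiseased
1,1,9
2,0,2
3,6,11
4,11,8
5,12,0
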