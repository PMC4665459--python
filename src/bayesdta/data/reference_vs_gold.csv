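# bayesdta: nogold
# hypothetical imperfect-reference example; reference R by new test T
reference,test,count
0,0,74
0,1,46
1,0,16
1,1,64
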