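# bayesdta: nogold
# reference = serology R, test = stool exam T; 162 refugees, no gold standard
reference,test,count
0,0,35
0,1,2
1,0,87
1,1,38
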