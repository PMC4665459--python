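# bayesdta: 2x2
# rows: exercise stress test result X; columns: coronary artery disease D
x,d0,d1
0,327,208
1,115,818
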