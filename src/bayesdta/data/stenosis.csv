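# bayesdta: paired
# test1 = CT, test2 = MRI; coronary segments, 58 stenosed / 236 healthy
# non-diseased cells are DERIVED by exhaustive reconstruction (see fixture doc)
group,test1,test2,count
diseased,0,0,12
diseased,0,1,0
diseased,1,0,10
diseased,1,1,36
nondiseased,0,0,168
nondiseased,0,1,0
nondiseased,1,0,30
nondiseased,1,1,38
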