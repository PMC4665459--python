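# bayesdta: paired
# test1 = CT, test2 = MRI; lung-cancer staging, 995 diseased / 435 not
group,test1,test2,count
diseased,0,0,22
diseased,0,1,191
diseased,1,0,30
diseased,1,1,752
nondiseased,0,0,148
nondiseased,0,1,167
nondiseased,1,0,49
nondiseased,1,1,71
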