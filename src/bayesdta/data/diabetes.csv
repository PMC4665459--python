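# bayesdta: scores
# blood glucose (mg/dl); label 1 = diabetic (59), 0 = non-diabetic (19)
value,label
123,1
129,1
115,1
131,1
119,1
111,1
129,1
127,1
118,1
111,1
131,1
118,1
126,1
130,1
122,1
112,1
122,1
128,1
123,1
119,1
132,1
118,1
126,1
136,1
118,1
122,1
119,1
117,1
129,1
120,1
125,1
115,1
131,1
123,1
130,1
113,1
128,1
138,1
119,1
118,1
124,1
127,1
139,1
120,1
122,1
120,1
114,1
114,1
122,1
127,1
123,1
118,1
131,1
130,1
139,1
125,1
135,1
121,1
124,1
109,0
106,0
100,0
88,0
106,0
108,0
110,0
111,0
112,0
94,0
122,0
110,0
113,0
106,0
114,0
101,0
99,0
128,0
106,0
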