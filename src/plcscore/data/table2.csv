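patient_id,post_vm,post_pgs,inf_pgs,ary,cric_lam,lcam,ctm,histology
1,1,0,0,0,0,0,0,0
2,1,1,1,0,0,1,0,0
3,2,2,0,0,0,0,0,0
4,0,1,1,0,0,1,0,0
5,1,1,0,0,0,1,0,0
6,2,0,2,0,2,2,2,1
7,0,1,1,0,0,1,0,0
8,2,1,1,0,0,2,0,1
9,2,2,2,1,0,2,0,1
10,2,2,2,1,0,2,1,1
11,2,1,1,1,0,1,1,1
12,2,1,0,0,0,0,0,0
13,1,0,0,0,0,0,0,0
14,0,0,0,0,0,0,0,0
15,2,0,0,0,0,1,0,1
16,2,2,1,2,0,1,0,1
17,2,1,0,0,0,0,0,1
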