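id,ic50_uM,kier_a2,slogp_vsa1,within_svm,low_confidence
II,41.7,4.5847445,7.7454643,1,0
IV,64.5,4.4210858,7.7454643,1,0
4,67.7,5.2678456,7.7454643,1,0
33,,4.4425101,5.6876111,0,0
39,59.8,5.5963559,0,1,0
40,,3.809427,5.6876111,0,0
42,,5.4008284,5.6876111,0,0
43,,5.4008284,5.6876111,0,0
53,,6.368185,5.6876111,0,0
54,48.9,8.1811314,0,1,0
57,,2.9886453,5.6876111,0,0
59,,2.0609839,0,0,0
60,66.7,7.5834055,0,1,0
65,,3.795996,0,0,0
68,,3.8128579,5.6876111,0,0
71,,5.9534798,7.7454643,0,0
72,,10.287,5.6876111,0,1
77,47,5.4362946,0,1,0
78,,16,0,0,0
79,,13.104808,0,0,0
81,,16.544603,0,0,0
83,25,11.143562,0,1,0
84,,12.104386,7.7454643,0,0
85,,8.1214361,20.749712,0,0
88,195.7,5.1365461,7.7454643,1,0
89,,11.143562,7.7454643,0,0
93,,5.4330149,5.2587838,0,0
94,,6.0677109,7.7454643,0,0
95,,5.9571776,7.7454643,0,0
96,,13.066667,0,0,0
98,43.2,3.932668,7.7454643,1,0
99,57,6.7910275,5.6876111,0,0
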