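id,length_m,embedded,reach,gravity,cross_body
1,0.350,Embedded,Reach,Ground-level,Large
2,0.320,Embedded,Return,Ground-level,Small
3,0.320,Virtual,Reach,Ground-level,Small
4,0.350,Virtual,Return,Ground-level,Large
5,0.415,Embedded,Reach,Against Gravity,Large
6,0.400,Embedded,Return,Towards Gravity,Small
7,0.400,Embedded,Reach,Against Gravity,Small
8,0.415,Embedded,Return,Towards Gravity,Large
9,0.276,Virtual,Reach,Against Gravity,Large
10,0.415,Virtual,Reach,Towards Gravity,Large
11,0.400,Virtual,Return,Against Gravity,Small
12,0.400,Embedded,Reach,Towards Gravity,Small
13,0.415,Virtual,Return,Against Gravity,Large
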