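participant,age,gender,dominant_hand,vision_correction
1,25,F,R,Y
2,24,F,R,N
3,32,F,R,Y
4,47,F,R,N
5,32,M,R,N
6,23,M,R,Y
7,40,M,R,N
8,27,M,R,Y
9,29,F,R,Y
10,29,M,R,Y
11,50,F,R,Y
12,33,F,R,Y
13,32,F,R,N
14,25,F,R,Y
15,39,M,R,N
16,26,M,R,Y
17,29,M,R,N
18,31,M,R,Y
19,32,F,R,Y
20,30,F,R,Y
21,26,F,R,N
22,27,F,R,Y
23,32,M,R,Y
24,60,F,R,Y
25,45,M,R,N
26,42,F,R,N
27,29,M,R,N
28,36,M,R,N
29,22,M,R,N
30,53,F,R,Y
31,24,F,R,Y
32,44,F,R,N
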