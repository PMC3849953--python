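participant,mode,iteration,seg,duration_s
2,AA1,1,1,4
2,AA1,1,2,4
2,AA1,1,3,4
2,AA1,1,4,4
2,AA1,1,5,4
2,AA1,1,6,4
2,AA1,1,7,4
2,AA1,1,8,4
2,AA1,1,9,4
2,AA1,1,10,4
2,AA1,1,11,4
2,AA1,1,12,4
2,AA1,1,13,4
2,AA2,1,1,3.4
2,AA2,1,2,3
2,AA2,1,3,3
2,AA2,1,4,3
2,AA2,1,5,3.6
2,AA2,1,6,3.8
2,AA2,1,7,3
2,AA2,1,8,3.8
2,AA2,1,9,3.4
2,AA2,1,10,3
2,AA2,1,11,3
2,AA2,1,12,3.6
2,AA2,1,13,3
2,AA2,2,1,2.4
2,AA2,2,2,2
2,AA2,2,3,2.2
2,AA2,2,4,2
2,AA2,2,5,2.6
2,AA2,2,6,2.8
2,AA2,2,7,2
2,AA2,2,8,2.8
2,AA2,2,9,2.6
2,AA2,2,10,2.8
2,AA2,2,11,1.8
2,AA2,2,12,2.6
2,AA2,2,13,2
2,AA2,3,1,2.2
2,AA2,3,2,1.6
2,AA2,3,3,1.8
2,AA2,3,4,1.6
2,AA2,3,5,2.4
2,AA2,3,6,1.8
2,AA2,3,7,1.8
2,AA2,3,8,1.8
2,AA2,3,9,2.2
2,AA2,3,10,2.8
2,AA2,3,11,1.6
2,AA2,3,12,2.2
2,AA2,3,13,1.6
2,AA2,4,1,1.6
2,AA2,4,2,1.6
2,AA2,4,3,1.6
2,AA2,4,4,1.2
2,AA2,4,5,2.4
2,AA2,4,6,1.6
2,AA2,4,7,1.6
2,AA2,4,8,1.6
2,AA2,4,9,2
2,AA2,4,10,2.6
2,AA2,4,11,1.2
2,AA2,4,12,2
2,AA2,4,13,1.6
2,AA2,5,1,1.8
2,AA2,5,2,1.6
2,AA2,5,3,1.6
2,AA2,5,4,1
2,AA2,5,5,2.4
2,AA2,5,6,1.6
2,AA2,5,7,1.6
2,AA2,5,8,1.6
2,AA2,5,9,1.8
2,AA2,5,10,2.6
2,AA2,5,11,1
2,AA2,5,12,2
2,AA2,5,13,1.6
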