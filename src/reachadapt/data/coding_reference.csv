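condition,category,symbol,is_reference
I,Virtual,EV0,1
I,Embedded,EV1,0
II,Return,RR0,1
II,Reach,RR1,0
III,Against Gravity,G0,1
III,Towards Gravity,G1,0
III,Ground Level,G2,0
IV,Large,CB0,1
IV,Small,CB1,0
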