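term,b,std_error,beta,t,sig
Constant,6.358,0.215,,29.597,0.000
Embedded,-3.477,0.167,-0.641,-20.841,0.000
Reach,4.433,0.167,0.817,26.606,0.000
Towards Gravity,0.117,0.289,0.020,0.404,0.686
Ground Level,1.831,0.167,0.312,10.991,0.000
Small,0.729,0.167,0.134,4.377,0.000
Participant 2,-1.563,0.242,-0.117,-6.470,0.000
Participant 3,3.003,0.249,0.211,12.065,0.000
Participant 4,1.471,0.249,0.103,5.909,0.000
Participant 5,0.838,0.271,0.050,3.092,0.002
Participant 6,4.903,0.258,0.319,18.978,0.000
Participant 7,2.891,0.258,0.188,11.190,0.000
Participant 8,-0.390,0.249,-0.027,-1.568,0.117
Participant 9,1.073,0.258,0.070,4.153,0.000
Participant 10,0.566,0.258,0.037,2.192,0.028
Participant 11,-0.662,0.249,-0.046,-2.658,0.008
Participant 12,2.362,0.258,0.154,9.145,0.000
Participant 13,5.587,0.258,0.364,21.626,0.000
Participant 14,-1.445,0.249,-0.101,-5.805,0.000
Participant 15,-0.340,0.258,-0.022,-1.316,0.188
Participant 16,-0.379,0.258,-0.025,-1.467,0.143
Participant 17,0.748,0.258,0.049,2.894,0.004
Participant 18,-0.597,0.258,-0.039,-2.309,0.021
Participant 19,-1.449,0.258,-0.094,-5.608,0.000
Participant 20,2.323,0.258,0.151,8.991,0.000
Participant 21,-2.114,0.258,-0.138,-8.184,0.000
Participant 22,2.230,0.258,0.145,8.632,0.000
Participant 23,2.091,0.249,0.147,8.402,0.000
Participant 24,0.264,0.258,0.017,1.022,0.307
Participant 25,-1.835,0.258,-0.119,-7.103,0.000
Participant 26,0.818,0.258,0.053,3.167,0.002
Participant 27,-0.930,0.258,-0.061,-3.600,0.000
Participant 30,-0.826,0.258,-0.054,-3.197,0.001
Participant 31,2.682,0.258,0.175,10.384,0.000
Participant 32,-0.065,0.258,-0.004,-0.253,0.800
EV1G1,4.193,0.334,0.653,12.569,0.000
EV1G2,2.831,0.264,0.377,10.732,0.000
RR1G1,-2.682,0.289,-0.358,-9.280,0.000
RR1G2,-3.759,0.204,-0.501,-18.401,0.000
RR1CB1,-1.361,0.236,-0.212,-5.770,0.000
G1CB1,-0.390,0.236,-0.052,-1.653,0.099
G2CB1,0.345,0.167,0.046,2.068,0.039
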