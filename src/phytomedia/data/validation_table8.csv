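response,medium,mean,sd,n
SN,R,3.6,1.12,45
SN,MS,3.6,1.01,45
SN,B5,3.51,1.1,45
SN,St,4.1,1.16,45
SN,Ha,4.04,0.82,45
SL,R,2.69,0.55,45
SL,MS,1.72,0.4,45
SL,B5,1.88,0.35,45
SL,St,3.41,1.2,45
SL,Ha,2.1,0.6,45
LA,R,34.06,10.29,45
LA,MS,29.58,7.62,45
LA,B5,21.43,6.86,45
LA,St,43.05,8.57,45
LA,Ha,38.39,11.04,45
SQ,R,4.51,0.51,45
SQ,MS,4.13,0.7,45
SQ,B5,3.22,0.6,45
SQ,St,4.02,0.27,45
SQ,Ha,3.87,0.46,45
BC,R,4.0,0.0,45
BC,MS,4.0,0.0,45
BC,B5,3.0,0.0,45
BC,St,3.6,0.5,45
BC,Ha,4.0,0.0,45
H,R,2.8,0.46,45
H,MS,2.64,0.68,45
H,B5,2.8,0.55,45
H,St,2.67,0.53,45
H,Ha,2.6,0.69,45
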