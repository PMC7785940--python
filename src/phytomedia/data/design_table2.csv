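treatment,nh4no3,kno3,mesos,micros,iron,replicate_of,is_control
1,0.51,0.66,1.65,1.5,3.04,,0
2,1.0,0.66,2.59,0.1,1.0,,0
3,1.0,1.0,2.37,1.5,1.08,,0
4,0.2,0.24,3.0,0.97,1.84,,0
5,0.9,0.1,0.25,0.1,1.6,,0
6,0.2,1.0,0.94,0.1,5.0,,0
7,0.2,1.0,0.94,0.1,5.0,6,0
8,0.4,1.0,0.25,1.5,1.0,,0
9,0.81,0.1,0.25,1.4,5.0,,0
10,1.0,1.0,3.0,0.39,5.0,,0
11,0.2,0.33,3.0,0.1,5.0,,0
12,0.81,0.1,0.25,1.4,5.0,,0
13,0.8,0.1,2.99,1.29,1.0,,0
14,0.4,0.1,0.25,0.1,5.0,,0
15,0.2,0.1,2.67,1.5,4.2,,0
16,1.0,0.33,0.25,1.5,1.0,,0
17,0.61,0.64,1.9,0.14,3.54,,0
18,0.2,0.76,0.25,0.1,1.0,,0
19,0.3,1.0,3.0,1.22,5.0,,0
20,1.0,0.1,2.38,0.1,4.46,,0
21,1.0,1.0,0.9,1.5,4.78,,0
22,0.2,0.76,0.25,1.5,5.0,,0
23,0.2,0.76,0.25,1.5,5.0,22,0
24,1.0,1.0,0.25,0.1,3.3,,0
25,1.0,0.35,1.52,0.94,3.1,,0
26,0.2,0.76,3.0,1.5,1.0,,0
27,0.24,1.0,3.0,0.1,2.0,,0
28,0.24,1.0,3.0,0.1,2.0,27,0
29,0.2,0.76,3.0,1.5,1.0,,0
30,0.32,0.1,2.34,0.1,1.0,,0
31,0.72,0.72,0.9,0.69,1.0,,0
32,0.2,0.1,0.8,1.36,1.0,,0
33,1.0,0.34,3.0,1.5,5.0,,0
34,1.0,1.0,1.0,1.0,1.0,,1
35,1.0,1.0,1.0,1.0,1.0,,1
36,1.0,1.0,1.0,1.0,1.0,,1
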