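media,NH4+,NO3-,K+,Ca2+,Mg2+,PO43-,SO42-,Cl-,Fe2+,BO3-,Mn2+,Zn2+,Cu2+,MoO22-,Na+,Co2+,I-,EDTA-,SN_mean,SN_sd,SL_mean,SL_sd,LA_mean,LA_sd,SQ_mean,SQ_sd,BC_mean,BC_sd,H_mean,H_sd
1,10.47,22.84,14.44,4.95,2.48,2.06,2.98,9.89,0.3,0.15,0.15,0.045,0.00015,0.0015,0.61,0.00016,0.0075,0.3,5.0,0.8,1.6,0.4,20.6,6.3,3.8,0.7,4.0,0.0,2.9,0.5
2,20.61,33.06,15.68,7.74,3.88,3.23,4.0,15.49,0.1,0.01,0.01,0.003,1e-05,0.0001,0.2,1e-05,0.0005,0.1,5.4,2.7,1.7,0.3,40.7,10.9,3.2,1.2,4.0,0.0,1.8,0.9
3,20.61,39.41,21.76,7.09,3.55,2.96,3.86,14.17,0.11,0.15,0.15,0.045,0.00015,0.0015,0.22,0.00016,0.0075,0.11,2.7,0.8,2.3,0.8,26.1,12.8,4.4,0.7,4.0,0.0,2.8,0.5
4,4.21,8.62,8.17,8.98,4.5,3.75,4.81,17.96,0.18,0.1,0.1,0.029,0.0001,0.001,0.37,0.0001,0.0048,0.18,5.8,2.6,1.9,0.6,12.0,4.0,3.5,0.5,4.0,0.0,1.8,1.0
5,18.55,20.43,2.19,0.75,0.38,0.31,0.55,1.5,0.16,0.01,0.01,0.003,1e-05,0.0001,0.32,1e-05,0.0005,0.16,5.8,1.6,1.2,0.3,7.1,3.4,3.1,0.5,4.0,0.0,3.0,0.0
6,4.12,22.92,19.96,2.81,1.41,1.17,1.92,5.61,0.5,0.01,0.01,0.003,1e-05,0.0001,1.0,1e-05,0.0005,0.5,2.6,1.1,1.2,0.4,6.8,3.2,2.5,0.9,4.0,0.0,3.0,0.0
7,4.12,22.92,19.96,2.81,1.41,1.17,1.92,5.61,0.5,0.01,0.01,0.003,1e-05,0.0001,1.0,1e-05,0.0005,0.5,2.2,1.2,1.4,0.5,7.8,4.4,2.2,0.9,4.0,0.0,3.0,0.0
8,8.25,27.04,19.11,0.75,0.38,0.31,0.67,1.5,0.1,0.15,0.15,0.045,0.00015,0.0015,0.2,0.00016,0.0075,0.1,7.9,2.7,1.1,0.2,8.7,3.9,2.8,0.5,3.5,0.5,2.9,0.3
9,16.73,18.61,2.2,0.75,0.38,0.31,1.06,1.5,0.5,0.14,0.14,0.042,0.00014,0.0014,1.0,0.00015,0.007,0.5,4.1,1.5,0.7,0.2,3.1,1.7,1.7,0.5,4.0,0.0,3.0,0.0
10,20.61,39.41,22.54,8.98,4.5,3.75,5.05,17.96,0.5,0.04,0.04,0.012,4e-05,0.0004,1.0,4e-05,0.0019,0.5,2.2,1.1,1.3,0.5,9.2,3.6,2.3,1.0,4.0,0.0,2.2,1.0
11,4.21,10.31,9.86,8.98,4.5,3.75,5.02,17.96,0.5,0.01,0.01,0.003,1e-05,0.0001,1.0,1e-05,0.0005,0.5,3.7,1.1,1.0,0.3,6.0,2.1,1.7,0.7,4.0,0.0,1.9,1.0
12,16.73,18.61,2.2,0.75,0.38,0.31,1.06,1.5,0.5,0.14,0.14,0.042,0.00014,0.0014,1.0,0.00015,0.007,0.5,4.2,1.5,0.8,0.2,3.8,1.2,1.5,0.5,3.1,0.2,3.0,0.0
13,16.57,18.45,5.62,8.94,4.48,3.73,4.75,17.88,0.1,0.13,0.13,0.039,0.00013,0.0013,0.2,0.00014,0.0064,0.1,4.8,1.0,1.7,0.4,17.0,5.5,3.6,0.7,4.0,0.0,1.9,0.7
14,8.16,10.04,2.19,0.75,0.38,0.31,0.89,1.5,0.5,0.01,0.01,0.003,1e-05,0.0001,1.0,1e-05,0.0005,0.5,3.1,1.4,0.7,0.3,3.1,1.3,1.0,0.0,3.0,0.0,3.0,0.0
15,4.12,6.0,5.22,7.99,4.01,3.34,4.62,15.98,0.42,0.15,0.15,0.045,0.00015,0.0015,0.84,0.00016,0.0075,0.42,1.9,0.8,1.1,0.3,4.1,1.8,1.3,0.6,4.0,0.0,2.9,0.3
16,20.61,26.89,6.6,0.75,0.38,0.31,0.67,1.5,0.1,0.15,0.15,0.045,0.00015,0.0015,0.2,0.00016,0.0075,0.1,6.0,1.2,1.5,0.4,14.0,3.4,3.1,0.6,3.9,0.2,2.6,0.7
17,12.66,24.76,14.47,5.69,2.85,2.37,3.23,11.37,0.35,0.01,0.01,0.004,1e-05,0.0001,0.71,1e-05,0.0007,0.35,1.9,1.1,1.2,0.4,8.7,2.3,2.3,0.9,4.0,0.0,3.0,0.0
18,4.12,18.35,14.54,0.75,0.38,0.31,0.49,1.5,0.1,0.01,0.01,0.003,1e-05,0.0001,0.2,1e-05,0.0005,0.1,6.1,1.4,1.3,0.3,8.8,2.8,2.9,0.5,2.0,0.0,2.9,0.3
19,6.26,25.05,22.55,8.98,4.5,3.75,5.16,17.96,0.5,0.12,0.12,0.036,0.00012,0.0013,1.0,0.00013,0.0061,0.5,2.9,1.5,1.7,0.7,14.5,6.4,3.4,1.0,4.0,0.0,2.7,0.8
20,20.61,22.49,4.85,7.13,3.57,2.97,4.03,14.25,0.45,0.01,0.01,0.003,1e-05,0.0001,0.89,1e-05,0.0005,0.45,1.9,0.9,1.5,0.6,6.1,3.7,2.1,0.7,4.0,0.0,2.9,0.3
21,20.61,39.41,19.92,2.68,1.35,1.12,2.02,5.37,0.48,0.15,0.15,0.045,0.00015,0.0015,0.96,0.00016,0.0075,0.48,1.1,0.3,1.7,0.3,5.7,3.4,2.3,1.0,4.0,0.0,3.0,0.0
22,4.12,18.35,14.55,0.75,0.38,0.31,1.07,1.5,0.5,0.15,0.15,0.045,0.00015,0.0015,1.0,0.00016,0.0075,0.5,4.3,0.9,1.0,0.2,4.1,1.4,1.7,0.5,1.0,0.0,3.0,0.0
23,4.12,18.35,14.55,0.75,0.38,0.31,1.07,1.5,0.5,0.15,0.15,0.045,0.00015,0.0015,1.0,0.00016,0.0075,0.5,3.2,1.3,1.0,0.3,4.0,1.6,1.7,0.5,1.2,0.7,3.0,0.0
24,20.61,39.41,19.11,0.75,0.38,0.31,0.72,1.5,0.33,0.01,0.01,0.003,1e-05,0.0001,0.66,1e-05,0.0005,0.33,3.1,1.5,1.3,0.4,4.7,2.0,1.9,0.8,4.0,0.0,2.6,0.9
25,20.61,27.14,8.43,4.53,2.27,1.89,2.71,9.07,0.31,0.09,0.09,0.028,9e-05,0.001,0.62,0.0001,0.0047,0.31,3.5,0.9,2.2,0.9,16.2,5.3,3.7,0.7,4.0,0.0,2.9,0.5
26,4.12,18.43,18.07,8.98,4.5,3.75,4.8,17.96,0.1,0.15,0.15,0.045,0.00015,0.0015,0.2,0.00016,0.0075,0.1,2.3,1.0,1.9,0.8,21.7,10.3,4.2,0.8,3.6,0.5,2.8,0.4
27,4.95,23.74,22.54,8.98,4.5,3.75,4.72,17.96,0.2,0.01,0.01,0.003,1e-05,0.0001,0.4,1e-05,0.0005,0.2,4.1,1.8,2.0,0.6,28.5,8.5,3.9,0.9,4.0,0.0,1.4,0.7
28,4.95,23.74,22.54,8.98,4.5,3.75,4.72,17.96,0.2,0.01,0.01,0.003,1e-05,0.0001,0.4,1e-05,0.0005,0.2,4.3,1.5,1.9,0.6,29.9,13.8,4.1,0.8,4.0,0.0,1.8,0.7
29,4.12,18.43,18.07,8.98,4.5,3.75,4.8,17.96,0.1,0.15,0.15,0.045,0.00015,0.0015,0.2,0.00016,0.0075,0.1,2.7,1.0,1.8,1.1,18.9,9.3,3.5,1.2,3.7,0.5,2.4,0.8
30,6.51,8.39,4.8,7.0,3.51,2.92,3.63,14.01,0.1,0.01,0.01,0.003,1e-05,0.0001,0.2,1e-05,0.0005,0.1,6.6,2.4,1.1,0.3,9.3,3.9,1.4,0.5,4.0,0.0,1.0,0.0
31,14.92,28.46,14.67,2.68,1.35,1.12,1.54,5.36,0.1,0.07,0.07,0.021,7e-05,0.0007,0.2,7e-05,0.0034,0.1,3.9,1.4,2.6,0.9,28.3,9.3,4.7,0.5,4.0,0.0,2.7,0.5
32,4.12,6.0,2.89,2.39,1.2,1.0,1.48,4.79,0.1,0.14,0.14,0.041,0.00014,0.0014,0.2,0.00014,0.0068,0.1,4.1,1.7,1.2,0.3,5.7,2.9,2.4,0.8,4.0,0.0,2.9,0.3
33,20.61,26.98,10.12,8.98,4.5,3.75,5.2,17.96,0.5,0.15,0.15,0.045,0.00015,0.0015,1.0,0.00016,0.0075,0.5,2.6,2.1,1.5,0.5,10.4,5.5,2.6,0.8,4.0,0.0,2.4,0.9
MS,20.61,39.41,20.05,2.99,1.5,1.25,1.73,5.99,0.1,0.1,0.1,0.03,0.0001,0.001,0.2,0.00011,0.005,0.1,3.9,1.3,1.7,0.4,28.7,9.3,4.1,0.4,4.0,0.0,2.6,0.6
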