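salt,R,MS,B5,St,Ha
KNO3,1604.18,1900.0,2500.0,1800.0,1900.0
NH4NO3,1297.09,1650.0,0.0,400.0,1650.0
(NH4)2SO4,0.0,0.0,134.0,0.0,0.0
Ca(NO3)2.4H2O,0.0,0.0,0.0,1200.0,0.0
CaCl2.2H2O,545.61,440.0,150.0,0.0,440.0
MgSO4.7H2O,926.54,370.0,250.0,360.0,370.0
KH2PO4,375.63,170.0,0.0,270.0,170.0
NaH2PO4.H2O,0.0,0.0,150.0,0.0,0.0
MnSO4.4H2O,5.63,22.3,13.2,1.0,25.0
ZnSO4.7H2O,2.97,8.6,2.0,8.6,10.0
H3BO3,5.07,6.2,3.0,6.2,10.0
KI,1.43,0.83,0.75,0.08,0.0
CuSO4.5H2O,0.05,0.025,0.025,0.025,0.025
Na2MoO4.2H2O,0.28,0.25,0.25,0.25,0.25
CoCl2.6H2O,0.04,0.025,0.025,0.025,0.0
FeSO4.7H2O,49.54,27.85,27.85,27.85,27.85
Na2EDTA.2H2O,53.88,37.25,37.25,37.25,37.25
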