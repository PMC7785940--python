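name,low,high,salts
nh4no3,0.2,1.0,NH4NO3
kno3,0.1,1.0,KNO3
mesos,0.25,3.0,CaCl2.2H2O;MgSO4.7H2O;KH2PO4
micros,0.1,1.5,MnSO4.4H2O;ZnSO4.7H2O;H3BO3;KI;CuSO4.5H2O;Na2MoO4.2H2O;CoCl2.6H2O
iron,1.0,5.0,FeSO4.7H2O;Na2EDTA.2H2O
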