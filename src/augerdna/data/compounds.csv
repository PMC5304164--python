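name,nuclide,linker,distance_docking_A,distance_md_A,d0_minus_1e13_per_ml,d0_minus_se,d0_plus_1e13_per_ml,d0_plus_se,y_minus_per_decay,y_minus_se,y_plus_per_decay,y_plus_se,prep_ug_per_ml
125I-C3,125I,C3,9.37,9.90,4.57,0.41,4.28,0.77,0.0730,0.0065,0.0790,0.0142,20.0
125I-C5,125I,C5,10.49,11.06,6.94,0.20,8.96,0.18,0.0480,0.0014,0.0370,0.0007,20.0
125I-C8,125I,C8,11.04,11.38,10.30,1.23,234.00,192.00,0.0330,0.0039,0.0010,0.0008,20.0
99mTc-C3,99mTc,C3,10.80,,3.33,0.50,5.00,0.45,0.0336,0.0050,0.0224,0.0020,6.6667
99mTc-C5,99mTc,C5,12.92,,33.30,6.32,50.00,3.00,0.0034,0.0006,0.0022,0.0001,6.6667
99mTc-C8,99mTc,C8,14.11,,16.70,1.50,33.30,2.00,0.0067,0.0006,0.0034,0.0002,6.6667
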