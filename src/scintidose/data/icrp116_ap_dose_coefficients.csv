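# Effective dose per photon fluence, anteroposterior (AP) irradiation,
# pSv*cm^2, transcribed from ICRP Publication 116, Table A.1 (AP column).
energy_keV,pSv_cm2
10,0.0685
15,0.156
20,0.225
30,0.313
40,0.351
50,0.37
60,0.391
70,0.413
80,0.443
100,0.519
150,0.748
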