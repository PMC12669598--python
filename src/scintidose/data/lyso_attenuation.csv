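# LYSO (Lu1.8Y0.2SiO5, density 7.1 g/cm3) linear attenuation coefficient
# Composition-weighted total mass attenuation transcribed from standard
# photon cross-section compilations (NIST XCOM totals, with coherent),
# converted to 1/mm. Grid brackets the Lu K-edge at 63.2/63.4 keV so
# interpolation never bridges the discontinuity.
energy_keV,mu_per_mm
10,68.525
12,51.298
15,33.09
20,18.657
25,10.96
30,7.0583
35,4.8093
40,3.4648
45,2.6249
50,2.0421
55,1.6507
60,1.3707
63.2,1.202
63.4,5.8988
70,4.6603
80,3.3211
90,2.4967
100,1.981
110,1.5948
120,1.3269
130,1.1156
140,0.95575
150,0.82689
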