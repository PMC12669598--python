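# lead linear attenuation coefficient, 1/mm, transcribed from
# standard photon cross-section compilations (NIST XCOM totals).
energy_keV,mu_per_mm
10,148.23
13.0,76.045
13.1,183.87
15,126.67
20,98.019
30,34.413
40,16.299
50,9.1265
60,5.6988
70,3.9611
80,2.7456
87.9,2.1679
88.1,8.7202
100,6.2981
120,4.3697
150,2.2859
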