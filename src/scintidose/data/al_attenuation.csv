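# aluminum linear attenuation coefficient, 1/mm, transcribed from
# standard photon cross-section compilations (NIST XCOM totals).
energy_keV,mu_per_mm
10,7.0795
15,2.1471
20,0.92873
30,0.30445
40,0.15344
50,0.09935
60,0.074978
80,0.054466
100,0.045991
120,0.041457
150,0.037192
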