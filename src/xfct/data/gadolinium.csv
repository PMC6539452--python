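# Elemental gadolinium (Z=64), mass attenuation (total, with coherent) and
# photoelectric component, transcribed from the NIST XCOM tabulation.
# K absorption edge at 50.24 keV: the table is split just below / just above
# the edge and must never be interpolated across it.
# Reference density 7.90 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g,photoelectric_cm2_per_g
20,27.80,27.56
25,14.50,14.31
30,8.56,8.36
35,5.49,5.31
40,3.76,3.58
45,2.70,2.53
50,2.01,1.85
50.2,1.99,1.83
50.3,9.22,9.06
55,7.15,7.00
60,5.52,5.38
70,3.56,3.42
80,2.44,2.30
100,1.32,1.19
120,0.82,0.70
150,0.48,0.36
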