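# Copper (beam filter material), mass attenuation transcribed from the NIST
# XCOM tabulation. Reference density 8.960 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g,photoelectric_cm2_per_g
20,33.790,33.400
30,10.920,10.600
40,4.8620,4.5700
50,2.6130,2.3500
60,1.5930,1.3600
80,0.7630,0.5760
100,0.4584,0.2970
150,0.2217,0.1020
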