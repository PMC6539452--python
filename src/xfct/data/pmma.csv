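# Polymethyl methacrylate (PMMA, C5H8O2), mass attenuation transcribed from
# the NIST XCOM tabulation. Reference density 1.190 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g,photoelectric_cm2_per_g
20,0.5714,0.3240
30,0.3032,0.0823
40,0.2350,0.0315
50,0.2074,0.0149
60,0.1924,0.0081
80,0.1751,0.0032
100,0.1641,0.0015
150,0.1456,0.0004
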