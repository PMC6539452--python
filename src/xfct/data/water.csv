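# Liquid water, mass attenuation (total, with coherent) and photoelectric
# component, transcribed from the NIST XCOM tabulation. Reference density
# 1.000 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g,photoelectric_cm2_per_g
20,0.8096,0.5190
30,0.3756,0.1330
40,0.2683,0.0512
50,0.2269,0.0243
60,0.2059,0.0133
80,0.1837,0.0052
100,0.1707,0.0025
150,0.1505,0.0007
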