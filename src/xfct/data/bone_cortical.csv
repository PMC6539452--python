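# Cortical bone (ICRU-44 composition), mass attenuation transcribed from the
# NIST tabulation. Reference density 1.920 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g,photoelectric_cm2_per_g
20,4.0010,3.6400
30,1.3310,1.0500
40,0.6655,0.4240
50,0.4242,0.2050
60,0.3148,0.1150
80,0.2229,0.0470
100,0.1855,0.0234
150,0.1480,0.0066
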