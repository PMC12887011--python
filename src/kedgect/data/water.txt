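# Total mass attenuation of liquid water.
# Source: NIST standard reference tables (Hubbell & Seltzer).
# columns: energy_keV  mu_over_rho_cm2_per_g
10.000000 5.32900000e+00
15.000000 1.67300000e+00
20.000000 8.09600000e-01
30.000000 3.75600000e-01
40.000000 2.68300000e-01
50.000000 2.26900000e-01
60.000000 2.05900000e-01
80.000000 1.83700000e-01
100.000000 1.70700000e-01
150.000000 1.50500000e-01
200.000000 1.37000000e-01
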