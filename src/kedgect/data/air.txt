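# Total mass attenuation of dry air (near sea level).
# Source: NIST standard reference tables (Hubbell & Seltzer).
# columns: energy_keV  mu_over_rho_cm2_per_g
10.000000 5.12000000e+00
15.000000 1.61400000e+00
20.000000 7.77900000e-01
30.000000 3.53800000e-01
40.000000 2.48500000e-01
50.000000 2.08000000e-01
60.000000 1.87500000e-01
80.000000 1.66200000e-01
100.000000 1.54100000e-01
150.000000 1.35600000e-01
200.000000 1.23300000e-01
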