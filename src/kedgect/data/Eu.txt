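# Total mass attenuation of Eu, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 9.00904195e+01
16.000000 7.59555380e+01
17.000000 6.46773506e+01
18.000000 5.55746850e+01
19.000000 4.81423475e+01
20.000000 4.20096671e+01
21.000000 3.69011073e+01
22.000000 3.26088425e+01
23.000000 2.89740369e+01
24.000000 2.58738274e+01
25.000000 2.32121132e+01
26.000000 2.09130086e+01
27.000000 1.89149246e+01
28.000000 1.71689039e+01
29.000000 1.56381295e+01
30.000000 1.42899327e+01
31.000000 1.30958991e+01
32.000000 1.20354563e+01
33.000000 1.10905664e+01
34.000000 1.02439520e+01
35.000000 9.48434935e+00
36.000000 8.79853688e+00
37.000000 8.18005140e+00
38.000000 7.62070977e+00
39.000000 7.11350561e+00
40.000000 6.65241490e+00
41.000000 6.23223778e+00
42.000000 5.84846890e+00
43.000000 5.49719075e+00
44.000000 5.17498545e+00
45.000000 4.87886138e+00
46.000000 4.60619207e+00
47.000000 4.35466482e+00
48.000000 4.12223762e+00
48.519000 4.00960397e+00
48.519000 1.99052214e+01
49.000000 1.94257237e+01
50.000000 1.84662135e+01
51.000000 1.75656536e+01
52.000000 1.67075223e+01
53.000000 1.59056980e+01
54.000000 1.51555771e+01
55.000000 1.44530047e+01
56.000000 1.37942243e+01
57.000000 1.31758335e+01
58.000000 1.25947453e+01
59.000000 1.20481543e+01
60.000000 1.15335071e+01
61.000000 1.10484756e+01
62.000000 1.05909347e+01
63.000000 1.01589411e+01
64.000000 9.75080450e+00
65.000000 9.36479102e+00
66.000000 8.99939804e+00
67.000000 8.65325164e+00
68.000000 8.32508730e+00
69.000000 8.01373971e+00
70.000000 7.71813385e+00
71.000000 7.43727680e+00
72.000000 7.17025046e+00
73.000000 6.91620507e+00
74.000000 6.67435325e+00
75.000000 6.44396473e+00
76.000000 6.22436150e+00
77.000000 6.01491351e+00
78.000000 5.81503471e+00
79.000000 5.62417948e+00
80.000000 5.44183941e+00
81.000000 5.26703309e+00
82.000000 5.09993051e+00
83.000000 4.94010661e+00
84.000000 4.78716443e+00
85.000000 4.64073292e+00
86.000000 4.50046497e+00
87.000000 4.36603565e+00
88.000000 4.23714055e+00
89.000000 4.11349426e+00
90.000000 3.99482899e+00
91.000000 3.88089334e+00
92.000000 3.77145109e+00
93.000000 3.66628017e+00
94.000000 3.56517167e+00
95.000000 3.46792889e+00
96.000000 3.37436656e+00
97.000000 3.28431008e+00
98.000000 3.19567543e+00
99.000000 3.11032888e+00
100.000000 3.02818926e+00
101.000000 2.94910504e+00
102.000000 2.87293332e+00
103.000000 2.79953921e+00
104.000000 2.72879528e+00
105.000000 2.66058113e+00
106.000000 2.59478292e+00
107.000000 2.53129296e+00
108.000000 2.47000931e+00
109.000000 2.41083543e+00
110.000000 2.35367984e+00
111.000000 2.29845585e+00
112.000000 2.24508120e+00
113.000000 2.19347787e+00
114.000000 2.14357177e+00
115.000000 2.09529252e+00
116.000000 2.04857327e+00
117.000000 2.00335047e+00
118.000000 1.95956364e+00
119.000000 1.91715528e+00
120.000000 1.87607063e+00
121.000000 1.83625755e+00
122.000000 1.79766637e+00
123.000000 1.76024975e+00
124.000000 1.72396254e+00
125.000000 1.68876170e+00
126.000000 1.65460614e+00
127.000000 1.62145665e+00
128.000000 1.58927578e+00
129.000000 1.55802777e+00
130.000000 1.52767843e+00
131.000000 1.49819509e+00
132.000000 1.46954649e+00
133.000000 1.44170275e+00
134.000000 1.41463527e+00
135.000000 1.38831665e+00
136.000000 1.36272069e+00
137.000000 1.33782226e+00
138.000000 1.31359731e+00
139.000000 1.29002276e+00
140.000000 1.26707650e+00
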