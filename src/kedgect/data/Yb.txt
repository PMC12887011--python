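# Total mass attenuation of Yb, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.18311945e+02
16.000000 1.00044127e+02
17.000000 8.54262717e+01
18.000000 7.35791723e+01
19.000000 6.38628338e+01
20.000000 5.58222449e+01
21.000000 4.91018644e+01
22.000000 4.34420446e+01
23.000000 3.86422728e+01
24.000000 3.45430647e+01
25.000000 3.10194465e+01
26.000000 2.79724861e+01
27.000000 2.53201574e+01
28.000000 2.29970876e+01
29.000000 2.09590625e+01
30.000000 1.91630400e+01
31.000000 1.75736242e+01
32.000000 1.61615155e+01
33.000000 1.49023119e+01
34.000000 1.37755728e+01
35.000000 1.27640836e+01
36.000000 1.18532727e+01
37.000000 1.10307459e+01
38.000000 1.02859142e+01
39.000000 9.60939288e+00
40.000000 8.99291248e+00
41.000000 8.43069735e+00
42.000000 7.91682072e+00
43.000000 7.44612350e+00
44.000000 7.01351118e+00
45.000000 6.61559123e+00
46.000000 6.24825753e+00
47.000000 5.90881467e+00
48.000000 5.59521031e+00
49.000000 5.30499605e+00
50.000000 5.03599903e+00
51.000000 4.78628627e+00
52.000000 4.55413405e+00
53.000000 4.33800186e+00
54.000000 4.13650989e+00
55.000000 3.94841969e+00
56.000000 3.77261749e+00
57.000000 3.60809972e+00
58.000000 3.45396037e+00
59.000000 3.30938010e+00
60.000000 3.17361662e+00
61.000000 3.04599637e+00
61.332300 3.00589031e+00
61.332300 1.36263782e+01
62.000000 1.32706532e+01
63.000000 1.27566060e+01
64.000000 1.22683910e+01
65.000000 1.17972784e+01
66.000000 1.13471922e+01
67.000000 1.09207872e+01
68.000000 1.05164989e+01
69.000000 1.01328867e+01
70.000000 9.76862245e+00
71.000000 9.42248039e+00
72.000000 9.09332780e+00
73.000000 8.78011690e+00
74.000000 8.48187744e+00
75.000000 8.19771001e+00
76.000000 7.92678004e+00
77.000000 7.66831237e+00
78.000000 7.42158629e+00
79.000000 7.18593115e+00
80.000000 6.96072228e+00
81.000000 6.74321436e+00
82.000000 6.53519035e+00
83.000000 6.33613098e+00
84.000000 6.14555107e+00
85.000000 5.96299694e+00
86.000000 5.78804406e+00
87.000000 5.62029481e+00
88.000000 5.45937657e+00
89.000000 5.30493982e+00
90.000000 5.15665653e+00
91.000000 5.01421859e+00
92.000000 4.87733642e+00
93.000000 4.74573765e+00
94.000000 4.61916594e+00
95.000000 4.49737990e+00
96.000000 4.38015204e+00
97.000000 4.26726788e+00
98.000000 4.15852504e+00
99.000000 4.05373246e+00
100.000000 3.95270969e+00
101.000000 3.85528617e+00
102.000000 3.76130060e+00
103.000000 3.67060038e+00
104.000000 3.58304104e+00
105.000000 3.49848574e+00
106.000000 3.41680481e+00
107.000000 3.33787530e+00
108.000000 3.26158058e+00
109.000000 3.18780996e+00
110.000000 3.11645835e+00
111.000000 3.04742589e+00
112.000000 2.98061771e+00
113.000000 2.91594359e+00
114.000000 2.85331769e+00
115.000000 2.79265835e+00
116.000000 2.73388780e+00
117.000000 2.67693199e+00
118.000000 2.62172034e+00
119.000000 2.56818558e+00
120.000000 2.51626356e+00
121.000000 2.46589307e+00
122.000000 2.41701570e+00
123.000000 2.36917006e+00
124.000000 2.32196300e+00
125.000000 2.27617241e+00
126.000000 2.23174457e+00
127.000000 2.18862825e+00
128.000000 2.14677451e+00
129.000000 2.10613662e+00
130.000000 2.06666993e+00
131.000000 2.02833175e+00
132.000000 1.99108128e+00
133.000000 1.95487947e+00
134.000000 1.91968898e+00
135.000000 1.88547406e+00
136.000000 1.85220049e+00
137.000000 1.81983548e+00
138.000000 1.78834761e+00
139.000000 1.75770680e+00
140.000000 1.72788418e+00
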