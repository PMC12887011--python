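# Total mass attenuation of Tb, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 9.72265996e+01
16.000000 8.20418368e+01
17.000000 6.99166114e+01
18.000000 6.01074926e+01
19.000000 5.20898736e+01
20.000000 4.54708819e+01
21.000000 3.99546768e+01
22.000000 3.53179647e+01
23.000000 3.13899771e+01
24.000000 2.80385415e+01
25.000000 2.51602309e+01
26.000000 2.26732927e+01
27.000000 2.05108365e+01
28.000000 1.86196850e+01
29.000000 1.69614553e+01
30.000000 1.55008268e+01
31.000000 1.42087808e+01
32.000000 1.30613185e+01
33.000000 1.20376700e+01
34.000000 1.11212528e+01
35.000000 1.02990693e+01
36.000000 9.55876377e+00
37.000000 8.88960788e+00
38.000000 8.28347125e+00
39.000000 7.73198639e+00
40.000000 7.23065702e+00
41.000000 6.77382439e+00
42.000000 6.35658614e+00
43.000000 5.97468008e+00
44.000000 5.62438805e+00
45.000000 5.30245597e+00
46.000000 5.00602723e+00
47.000000 4.73258673e+00
48.000000 4.47991394e+00
49.000000 4.24604306e+00
50.000000 4.02922946e+00
51.000000 3.82792092e+00
51.995700 3.64241290e+00
51.995700 1.76703680e+01
52.000000 1.76709587e+01
53.000000 1.68526696e+01
54.000000 1.60827879e+01
55.000000 1.53508335e+01
56.000000 1.46549816e+01
57.000000 1.40016846e+01
58.000000 1.33876939e+01
59.000000 1.28100572e+01
60.000000 1.22660870e+01
61.000000 1.17533332e+01
62.000000 1.12695588e+01
63.000000 1.08127184e+01
64.000000 1.03809389e+01
65.000000 9.97250323e+00
66.000000 9.58583473e+00
67.000000 9.21948414e+00
68.000000 8.87220383e+00
69.000000 8.54276562e+00
70.000000 8.22989852e+00
71.000000 7.93256164e+00
72.000000 7.64979225e+00
73.000000 7.38069902e+00
74.000000 7.12445583e+00
75.000000 6.88029627e+00
76.000000 6.64750860e+00
77.000000 6.42543123e+00
78.000000 6.21344864e+00
79.000000 6.01098760e+00
80.000000 5.81751385e+00
81.000000 5.63171792e+00
82.000000 5.45408428e+00
83.000000 5.28416359e+00
84.000000 5.12153610e+00
85.000000 4.96580945e+00
86.000000 4.81661657e+00
87.000000 4.67361377e+00
88.000000 4.53647904e+00
89.000000 4.40491046e+00
90.000000 4.27862470e+00
91.000000 4.15735573e+00
92.000000 4.04085359e+00
93.000000 3.92888325e+00
94.000000 3.82122356e+00
95.000000 3.71766633e+00
96.000000 3.61801540e+00
97.000000 3.52208588e+00
98.000000 3.42970338e+00
99.000000 3.34070330e+00
100.000000 3.25493019e+00
101.000000 3.17223719e+00
102.000000 3.09248546e+00
103.000000 3.01554366e+00
104.000000 2.94127219e+00
105.000000 2.86788632e+00
106.000000 2.79710116e+00
107.000000 2.72880070e+00
108.000000 2.66287510e+00
109.000000 2.59922036e+00
110.000000 2.53773795e+00
111.000000 2.47833447e+00
112.000000 2.42092135e+00
113.000000 2.36541452e+00
114.000000 2.31173420e+00
115.000000 2.25980461e+00
116.000000 2.20955375e+00
117.000000 2.16091317e+00
118.000000 2.11381777e+00
119.000000 2.06820563e+00
120.000000 2.02401778e+00
121.000000 1.98119809e+00
122.000000 1.93969309e+00
123.000000 1.89945179e+00
124.000000 1.86042562e+00
125.000000 1.82256824e+00
126.000000 1.78583540e+00
127.000000 1.75018492e+00
128.000000 1.71557647e+00
129.000000 1.68197157e+00
130.000000 1.64933342e+00
131.000000 1.61762685e+00
132.000000 1.58681823e+00
133.000000 1.55687540e+00
134.000000 1.52776757e+00
135.000000 1.49946527e+00
136.000000 1.47194030e+00
137.000000 1.44516562e+00
138.000000 1.41911534e+00
139.000000 1.39376465e+00
140.000000 1.36908973e+00
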