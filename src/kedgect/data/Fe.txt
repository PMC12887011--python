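# Total mass attenuation of Fe, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 5.68067276e+01
16.000000 4.75193397e+01
17.000000 4.01592099e+01
18.000000 3.42516176e+01
19.000000 2.94540826e+01
20.000000 2.55169108e+01
21.000000 2.22550724e+01
22.000000 1.95294332e+01
23.000000 1.72339739e+01
24.000000 1.52869277e+01
25.000000 1.36245329e+01
26.000000 1.21965630e+01
27.000000 1.09619417e+01
28.000000 9.88819132e+00
29.000000 8.95228253e+00
30.000000 8.13275190e+00
31.000000 7.41097949e+00
32.000000 6.76969493e+00
33.000000 6.20205020e+00
34.000000 5.69775188e+00
35.000000 5.24818801e+00
36.000000 4.84611570e+00
37.000000 4.48541354e+00
38.000000 4.16088382e+00
39.000000 3.86809387e+00
40.000000 3.60324764e+00
41.000000 3.36308151e+00
42.000000 3.14477912e+00
43.000000 2.94590138e+00
44.000000 2.76432882e+00
45.000000 2.59821372e+00
46.000000 2.44594030e+00
47.000000 2.30609147e+00
48.000000 2.17742083e+00
49.000000 2.05882922e+00
50.000000 1.94934474e+00
51.000000 1.84810594e+00
52.000000 1.75434739e+00
53.000000 1.66738747e+00
54.000000 1.58661779e+00
55.000000 1.51149425e+00
56.000000 1.44152917e+00
57.000000 1.37628461e+00
58.000000 1.31536657e+00
59.000000 1.25841990e+00
60.000000 1.20512391e+00
61.000000 1.15518853e+00
62.000000 1.10835095e+00
63.000000 1.06437270e+00
64.000000 1.02303701e+00
65.000000 9.84146580e-01
66.000000 9.47521562e-01
67.000000 9.12997775e-01
68.000000 8.80425137e-01
69.000000 8.49666278e-01
70.000000 8.20595291e-01
71.000000 7.93096645e-01
72.000000 7.67064179e-01
73.000000 7.42400251e-01
74.000000 7.19014930e-01
75.000000 6.96825302e-01
76.000000 6.75754845e-01
77.000000 6.55732852e-01
78.000000 6.36693922e-01
79.000000 6.18577505e-01
80.000000 6.01327486e-01
81.000000 5.84891807e-01
82.000000 5.69222133e-01
83.000000 5.54273538e-01
84.000000 5.40004237e-01
85.000000 5.26375322e-01
86.000000 5.13350544e-01
87.000000 5.00896093e-01
88.000000 4.88980414e-01
89.000000 4.77574031e-01
90.000000 4.66649394e-01
91.000000 4.56180723e-01
92.000000 4.46143892e-01
93.000000 4.36516286e-01
94.000000 4.27276712e-01
95.000000 4.18405284e-01
96.000000 4.09883330e-01
97.000000 4.01693310e-01
98.000000 3.93818737e-01
99.000000 3.86244099e-01
100.000000 3.78954799e-01
101.000000 3.71937084e-01
102.000000 3.65178001e-01
103.000000 3.58665326e-01
104.000000 3.52387533e-01
105.000000 3.46333738e-01
106.000000 3.40493664e-01
107.000000 3.34857594e-01
108.000000 3.29416343e-01
109.000000 3.24161220e-01
110.000000 3.19083997e-01
111.000000 3.14176886e-01
112.000000 3.09432504e-01
113.000000 3.04843855e-01
114.000000 3.00404301e-01
115.000000 2.96107546e-01
116.000000 2.91947611e-01
117.000000 2.87918818e-01
118.000000 2.84015775e-01
119.000000 2.80233351e-01
120.000000 2.76566671e-01
121.000000 2.73011097e-01
122.000000 2.69562209e-01
123.000000 2.66215805e-01
124.000000 2.62967880e-01
125.000000 2.59814616e-01
126.000000 2.56752374e-01
127.000000 2.53777684e-01
128.000000 2.50887236e-01
129.000000 2.48077869e-01
130.000000 2.45346566e-01
131.000000 2.42690447e-01
132.000000 2.40106757e-01
133.000000 2.37592865e-01
134.000000 2.35146257e-01
135.000000 2.32764524e-01
136.000000 2.30445365e-01
137.000000 2.28186576e-01
138.000000 2.25986047e-01
139.000000 2.23841759e-01
140.000000 2.21751774e-01
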