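# Total mass attenuation of Sm, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 8.55718858e+01
16.000000 7.21124327e+01
17.000000 6.13886212e+01
18.000000 5.27373340e+01
19.000000 4.56754436e+01
20.000000 3.98498403e+01
21.000000 3.49981366e+01
22.000000 3.09224920e+01
23.000000 2.74717494e+01
24.000000 2.45289938e+01
25.000000 2.20028798e+01
26.000000 1.98212220e+01
27.000000 1.79256516e+01
28.000000 1.62698096e+01
29.000000 1.48182303e+01
30.000000 1.35373747e+01
31.000000 1.24047697e+01
32.000000 1.13988253e+01
33.000000 1.05014578e+01
34.000000 9.69789605e+00
35.000000 8.97596596e+00
36.000000 8.32688652e+00
37.000000 7.74156188e+00
38.000000 7.21223927e+00
39.000000 6.73228123e+00
40.000000 6.29598141e+00
41.000000 5.89841437e+00
42.000000 5.53531280e+00
43.000000 5.20296635e+00
44.000000 4.89813802e+00
45.000000 4.61799468e+00
46.000000 4.36004907e+00
46.834200 4.16142066e+00
46.834200 2.08898603e+01
47.000000 2.07125761e+01
48.000000 1.96524000e+01
49.000000 1.86609612e+01
50.000000 1.77154187e+01
51.000000 1.68312629e+01
52.000000 1.60063109e+01
53.000000 1.52356257e+01
54.000000 1.45147615e+01
55.000000 1.38397065e+01
56.000000 1.32068342e+01
57.000000 1.26128604e+01
58.000000 1.20548063e+01
59.000000 1.15299648e+01
60.000000 1.10358726e+01
61.000000 1.05703010e+01
62.000000 1.01312945e+01
63.000000 9.71684040e+00
64.000000 9.32522729e+00
65.000000 8.95488605e+00
66.000000 8.60437631e+00
67.000000 8.27237416e+00
68.000000 7.95766126e+00
69.000000 7.65911504e+00
70.000000 7.37570002e+00
71.000000 7.10645993e+00
72.000000 6.85051071e+00
73.000000 6.60703417e+00
74.000000 6.37527231e+00
75.000000 6.15452217e+00
76.000000 5.94413119e+00
77.000000 5.74349307e+00
78.000000 5.55204386e+00
79.000000 5.36925863e+00
80.000000 5.19464827e+00
81.000000 5.02737599e+00
82.000000 4.86748806e+00
83.000000 4.71457654e+00
84.000000 4.56826045e+00
85.000000 4.42818374e+00
86.000000 4.29401335e+00
87.000000 4.16543750e+00
88.000000 4.04216414e+00
89.000000 3.92391945e+00
90.000000 3.81044655e+00
91.000000 3.70150428e+00
92.000000 3.59686607e+00
93.000000 3.49631893e+00
94.000000 3.39893425e+00
95.000000 3.30392211e+00
96.000000 3.21262943e+00
97.000000 3.12487331e+00
98.000000 3.04048163e+00
99.000000 2.95929231e+00
100.000000 2.88115262e+00
101.000000 2.80591856e+00
102.000000 2.73345428e+00
103.000000 2.66363155e+00
104.000000 2.59632925e+00
105.000000 2.53143292e+00
106.000000 2.46883434e+00
107.000000 2.40843112e+00
108.000000 2.35012636e+00
109.000000 2.29382825e+00
110.000000 2.23944985e+00
111.000000 2.18690869e+00
112.000000 2.13612660e+00
113.000000 2.08702937e+00
114.000000 2.03954655e+00
115.000000 1.99361123e+00
116.000000 1.94915984e+00
117.000000 1.90613193e+00
118.000000 1.86447001e+00
119.000000 1.82411939e+00
120.000000 1.78502799e+00
121.000000 1.74714623e+00
122.000000 1.71042687e+00
123.000000 1.67482488e+00
124.000000 1.64029733e+00
125.000000 1.60680329e+00
126.000000 1.57430367e+00
127.000000 1.54276118e+00
128.000000 1.51214020e+00
129.000000 1.48240672e+00
130.000000 1.45352821e+00
131.000000 1.42547360e+00
132.000000 1.39821317e+00
133.000000 1.37171848e+00
134.000000 1.34596233e+00
135.000000 1.32091866e+00
136.000000 1.29656254e+00
137.000000 1.27287008e+00
138.000000 1.24981838e+00
139.000000 1.22738551e+00
140.000000 1.20555042e+00
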