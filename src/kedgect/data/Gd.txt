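# Total mass attenuation of Gd, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 9.24784642e+01
16.000000 7.80100925e+01
17.000000 6.64540580e+01
18.000000 5.71157825e+01
19.000000 4.94885510e+01
20.000000 4.31931892e+01
21.000000 3.79477108e+01
22.000000 3.35393343e+01
23.000000 2.98053712e+01
24.000000 2.66199329e+01
25.000000 2.38845324e+01
26.000000 2.15213358e+01
27.000000 1.94668774e+01
28.000000 1.76707054e+01
29.000000 1.60958336e+01
30.000000 1.47086884e+01
31.000000 1.34816897e+01
32.000000 1.23908556e+01
33.000000 1.14180746e+01
34.000000 1.05481989e+01
35.000000 9.76675355e+00
36.000000 9.06312084e+00
37.000000 8.42637462e+00
38.000000 7.84973481e+00
39.000000 7.32683976e+00
40.000000 6.85147939e+00
41.000000 6.41829348e+00
42.000000 6.02263800e+00
43.000000 5.66047494e+00
44.000000 5.32828142e+00
45.000000 5.02297395e+00
46.000000 4.74184539e+00
47.000000 4.48251206e+00
48.000000 4.24286924e+00
49.000000 4.02105347e+00
50.000000 3.81541086e+00
50.239100 3.76944441e+00
50.239100 1.85248406e+01
51.000000 1.78436533e+01
52.000000 1.69921007e+01
53.000000 1.61893289e+01
54.000000 1.54282151e+01
55.000000 1.47152255e+01
56.000000 1.40465651e+01
57.000000 1.34187964e+01
58.000000 1.28288000e+01
59.000000 1.22737406e+01
60.000000 1.17510372e+01
61.000000 1.12583363e+01
62.000000 1.07934890e+01
63.000000 1.03545303e+01
64.000000 9.93966080e+00
65.000000 9.54723048e+00
66.000000 9.17581821e+00
67.000000 8.82395206e+00
68.000000 8.49030665e+00
69.000000 8.17370448e+00
70.000000 7.87305900e+00
71.000000 7.58736647e+00
72.000000 7.31569863e+00
73.000000 7.05719611e+00
74.000000 6.81106252e+00
75.000000 6.57655907e+00
76.000000 6.35299972e+00
77.000000 6.13974686e+00
78.000000 5.93620729e+00
79.000000 5.74182863e+00
80.000000 5.55609610e+00
81.000000 5.37786030e+00
82.000000 5.20746684e+00
83.000000 5.04448348e+00
84.000000 4.88850650e+00
85.000000 4.73915855e+00
86.000000 4.59608660e+00
87.000000 4.45896015e+00
88.000000 4.32746956e+00
89.000000 4.20132449e+00
90.000000 4.08025255e+00
91.000000 3.96399796e+00
92.000000 3.85232040e+00
93.000000 3.74499393e+00
94.000000 3.64180597e+00
95.000000 3.54255639e+00
96.000000 3.44705667e+00
97.000000 3.35512909e+00
98.000000 3.26660604e+00
99.000000 3.18132935e+00
100.000000 3.09914965e+00
101.000000 3.01895989e+00
102.000000 2.94083170e+00
103.000000 2.86555282e+00
104.000000 2.79299252e+00
105.000000 2.72302724e+00
106.000000 2.65554018e+00
107.000000 2.59042082e+00
108.000000 2.52756456e+00
109.000000 2.46687236e+00
110.000000 2.40825037e+00
111.000000 2.35160962e+00
112.000000 2.29686574e+00
113.000000 2.24393866e+00
114.000000 2.19275239e+00
115.000000 2.14323472e+00
116.000000 2.09531708e+00
117.000000 2.04893425e+00
118.000000 2.00402421e+00
119.000000 1.96052797e+00
120.000000 1.91838935e+00
121.000000 1.87755487e+00
122.000000 1.83797359e+00
123.000000 1.79959692e+00
124.000000 1.76237859e+00
125.000000 1.72627442e+00
126.000000 1.69124228e+00
127.000000 1.65724195e+00
128.000000 1.62423502e+00
129.000000 1.59218480e+00
130.000000 1.56105623e+00
131.000000 1.53081581e+00
132.000000 1.50143147e+00
133.000000 1.47287256e+00
134.000000 1.44510975e+00
135.000000 1.41811495e+00
136.000000 1.39186128e+00
137.000000 1.36632297e+00
138.000000 1.34147534e+00
139.000000 1.31729474e+00
140.000000 1.29375849e+00
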