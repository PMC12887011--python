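# Total mass attenuation of Ta, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.32405819e+02
16.000000 1.12098971e+02
17.000000 9.58261032e+01
18.000000 8.26222205e+01
19.000000 7.17882337e+01
20.000000 6.28076329e+01
21.000000 5.52941169e+01
22.000000 4.89608578e+01
23.000000 4.35798791e+01
24.000000 3.89781764e+01
25.000000 3.50194926e+01
26.000000 3.15942885e+01
27.000000 2.86102516e+01
28.000000 2.59936449e+01
29.000000 2.36971708e+01
30.000000 2.16726453e+01
31.000000 1.98804146e+01
32.000000 1.82876325e+01
33.000000 1.68669260e+01
34.000000 1.55953526e+01
35.000000 1.44535803e+01
36.000000 1.34252368e+01
37.000000 1.24963902e+01
38.000000 1.16551321e+01
39.000000 1.08912401e+01
40.000000 1.01959042e+01
41.000000 9.56150213e+00
42.000000 8.98141567e+00
43.000000 8.44970628e+00
44.000000 7.96085789e+00
45.000000 7.51128879e+00
46.000000 7.09707639e+00
47.000000 6.71476319e+00
48.000000 6.36129323e+00
49.000000 6.03356426e+00
50.000000 5.72952700e+00
51.000000 5.44682296e+00
52.000000 5.18342121e+00
53.000000 4.93820414e+00
54.000000 4.70960495e+00
55.000000 4.49621746e+00
56.000000 4.29677701e+00
57.000000 4.11014414e+00
58.000000 3.93529027e+00
59.000000 3.77128519e+00
60.000000 3.61728631e+00
61.000000 3.47252899e+00
62.000000 3.33631835e+00
63.000000 3.20802183e+00
64.000000 3.08706277e+00
65.000000 2.97291469e+00
66.000000 2.86509622e+00
67.000000 2.76316670e+00
67.416400 2.72284714e+00
67.416400 1.17909363e+01
68.000000 1.15507034e+01
69.000000 1.11495882e+01
70.000000 1.07655429e+01
71.000000 1.03951905e+01
72.000000 1.00351172e+01
73.000000 9.69236253e+00
74.000000 9.36587985e+00
75.000000 9.05469855e+00
76.000000 8.75791753e+00
77.000000 8.47469934e+00
78.000000 8.20426505e+00
79.000000 7.94588940e+00
80.000000 7.69889655e+00
81.000000 7.46282859e+00
82.000000 7.23686009e+00
83.000000 7.02044885e+00
84.000000 6.81308759e+00
85.000000 6.61430136e+00
86.000000 6.42364515e+00
87.000000 6.24070165e+00
88.000000 6.06460382e+00
89.000000 5.89471927e+00
90.000000 5.73159098e+00
91.000000 5.57488086e+00
92.000000 5.42427119e+00
93.000000 5.27946312e+00
94.000000 5.14017538e+00
95.000000 5.00614312e+00
96.000000 4.87711671e+00
97.000000 4.75286082e+00
98.000000 4.63315338e+00
99.000000 4.51778476e+00
100.000000 4.40655693e+00
101.000000 4.29928275e+00
102.000000 4.19578521e+00
103.000000 4.09589687e+00
104.000000 3.99945918e+00
105.000000 3.90632198e+00
106.000000 3.81634297e+00
107.000000 3.72938722e+00
108.000000 3.64532673e+00
109.000000 3.56404004e+00
110.000000 3.48541177e+00
111.000000 3.40933237e+00
112.000000 3.33569769e+00
113.000000 3.26440869e+00
114.000000 3.19537117e+00
115.000000 3.12849550e+00
116.000000 3.06369630e+00
117.000000 3.00089229e+00
118.000000 2.94000598e+00
119.000000 2.88096353e+00
120.000000 2.82369451e+00
121.000000 2.76813173e+00
122.000000 2.71421106e+00
123.000000 2.66187127e+00
124.000000 2.61105389e+00
125.000000 2.56170303e+00
126.000000 2.51376529e+00
127.000000 2.46718961e+00
128.000000 2.42192713e+00
129.000000 2.37793112e+00
130.000000 2.33515686e+00
131.000000 2.29356151e+00
132.000000 2.25310404e+00
133.000000 2.21374515e+00
134.000000 2.17544717e+00
135.000000 2.13801756e+00
136.000000 2.10083483e+00
137.000000 2.06466803e+00
138.000000 2.02948203e+00
139.000000 1.99524314e+00
140.000000 1.96191908e+00
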