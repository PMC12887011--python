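# Total mass attenuation of I, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 5.43085519e+01
16.000000 4.56720356e+01
17.000000 3.88112054e+01
18.000000 3.32872333e+01
19.000000 2.87870507e+01
20.000000 2.50812082e+01
21.000000 2.19993406e+01
22.000000 1.94142064e+01
23.000000 1.72294926e+01
24.000000 1.53700990e+01
25.000000 1.37774118e+01
26.000000 1.24046714e+01
27.000000 1.12111217e+01
28.000000 1.01644282e+01
29.000000 9.24939724e+00
30.000000 8.44568741e+00
31.000000 7.73664739e+00
32.000000 7.10855266e+00
33.000000 6.55001859e+00
33.169400 6.46417377e+00
33.169400 3.59453776e+01
34.000000 3.37211004e+01
35.000000 3.12748630e+01
36.000000 2.90724720e+01
37.000000 2.70756453e+01
38.000000 2.52606895e+01
39.000000 2.36071437e+01
40.000000 2.20972726e+01
41.000000 2.07156491e+01
42.000000 1.94488087e+01
43.000000 1.82849623e+01
44.000000 1.72122555e+01
45.000000 1.62232472e+01
46.000000 1.53100438e+01
47.000000 1.44654530e+01
48.000000 1.36830921e+01
49.000000 1.29572832e+01
50.000000 1.22829634e+01
51.000000 1.16556080e+01
52.000000 1.10711646e+01
53.000000 1.05259962e+01
54.000000 1.00168320e+01
55.000000 9.54072495e+00
56.000000 9.09501461e+00
57.000000 8.67729517e+00
58.000000 8.28538720e+00
59.000000 7.91731304e+00
60.000000 7.57127529e+00
61.000000 7.24563774e+00
62.000000 6.93890874e+00
63.000000 6.64972643e+00
64.000000 6.37684561e+00
65.000000 6.11912629e+00
66.000000 5.87552336e+00
67.000000 5.64472297e+00
68.000000 5.42612914e+00
69.000000 5.21911896e+00
70.000000 5.02292869e+00
71.000000 4.83685462e+00
72.000000 4.66024757e+00
73.000000 4.49250803e+00
74.000000 4.33308175e+00
75.000000 4.18145580e+00
76.000000 4.03715495e+00
77.000000 3.89973853e+00
78.000000 3.76879749e+00
79.000000 3.64395174e+00
80.000000 3.52484784e+00
81.000000 3.40949932e+00
82.000000 3.29945765e+00
83.000000 3.19441766e+00
84.000000 3.09409515e+00
85.000000 2.99822520e+00
86.000000 2.90656065e+00
87.000000 2.81887072e+00
88.000000 2.73493978e+00
89.000000 2.65456616e+00
90.000000 2.57756112e+00
91.000000 2.50374789e+00
92.000000 2.43296079e+00
93.000000 2.36504441e+00
94.000000 2.29985289e+00
95.000000 2.23724924e+00
96.000000 2.17710468e+00
97.000000 2.11929812e+00
98.000000 2.06371559e+00
99.000000 2.01024976e+00
100.000000 1.95879952e+00
101.000000 1.90926952e+00
102.000000 1.86156980e+00
103.000000 1.81561547e+00
104.000000 1.77132633e+00
105.000000 1.72862661e+00
106.000000 1.68744465e+00
107.000000 1.64771268e+00
108.000000 1.60936652e+00
109.000000 1.57234543e+00
110.000000 1.53659184e+00
111.000000 1.50205117e+00
112.000000 1.46867167e+00
113.000000 1.43640423e+00
114.000000 1.40520223e+00
115.000000 1.37502138e+00
116.000000 1.34581961e+00
117.000000 1.31755694e+00
118.000000 1.29019532e+00
119.000000 1.26369856e+00
120.000000 1.23803221e+00
121.000000 1.21316348e+00
122.000000 1.18906111e+00
123.000000 1.16569533e+00
124.000000 1.14303774e+00
125.000000 1.12106127e+00
126.000000 1.09974007e+00
127.000000 1.07904950e+00
128.000000 1.05896599e+00
129.000000 1.03946707e+00
130.000000 1.02053123e+00
131.000000 1.00213795e+00
132.000000 9.84267561e-01
133.000000 9.66901287e-01
134.000000 9.50021147e-01
135.000000 9.33609932e-01
136.000000 9.17651166e-01
137.000000 9.02129066e-01
138.000000 8.87028511e-01
139.000000 8.72335010e-01
140.000000 8.58034667e-01
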