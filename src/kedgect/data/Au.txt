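# Total mass attenuation of Au, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.62672031e+02
16.000000 1.38099346e+02
17.000000 1.18341396e+02
18.000000 1.02261618e+02
19.000000 8.90272009e+01
20.000000 7.80351297e+01
21.000000 6.88227360e+01
22.000000 6.10392916e+01
23.000000 5.44145937e+01
24.000000 4.87378323e+01
25.000000 4.38429616e+01
26.000000 3.95993847e+01
27.000000 3.58974285e+01
28.000000 3.26466682e+01
29.000000 2.97863366e+01
30.000000 2.72596263e+01
31.000000 2.50211854e+01
32.000000 2.30304825e+01
33.000000 2.12537018e+01
34.000000 1.96624706e+01
35.000000 1.82328566e+01
36.000000 1.69445726e+01
37.000000 1.57803399e+01
38.000000 1.47253769e+01
39.000000 1.37669851e+01
40.000000 1.28942121e+01
41.000000 1.20975760e+01
42.000000 1.13688385e+01
43.000000 1.07008177e+01
44.000000 1.00872320e+01
45.000000 9.52257078e+00
46.000000 9.00198510e+00
47.000000 8.52119664e+00
48.000000 8.07642023e+00
49.000000 7.66429845e+00
50.000000 7.28184597e+00
51.000000 6.92640197e+00
52.000000 6.59543598e+00
53.000000 6.28675496e+00
54.000000 5.99875208e+00
55.000000 5.72969751e+00
56.000000 5.47803395e+00
57.000000 5.24235672e+00
58.000000 5.02139654e+00
59.000000 4.81400440e+00
60.000000 4.61904769e+00
61.000000 4.43560558e+00
62.000000 4.26291831e+00
63.000000 4.09993180e+00
64.000000 3.94618858e+00
65.000000 3.80109388e+00
66.000000 3.66403778e+00
67.000000 3.53446182e+00
68.000000 3.41185389e+00
69.000000 3.29574384e+00
70.000000 3.18569943e+00
71.000000 3.08132282e+00
72.000000 2.98224741e+00
73.000000 2.88813496e+00
74.000000 2.79867307e+00
75.000000 2.71357289e+00
76.000000 2.63256705e+00
77.000000 2.55540780e+00
78.000000 2.48186535e+00
79.000000 2.41172639e+00
80.000000 2.34479262e+00
80.724900 2.29848727e+00
80.724900 8.98121873e+00
81.000000 8.90899810e+00
82.000000 8.64863361e+00
83.000000 8.39889052e+00
84.000000 8.15922536e+00
85.000000 7.92912810e+00
86.000000 7.70811978e+00
87.000000 7.49575024e+00
88.000000 7.29159613e+00
89.000000 7.09525907e+00
90.000000 6.90636386e+00
91.000000 6.72455701e+00
92.000000 6.54950516e+00
93.000000 6.37996030e+00
94.000000 6.21667733e+00
95.000000 6.05940373e+00
96.000000 5.90786093e+00
97.000000 5.76178594e+00
98.000000 5.62093025e+00
99.000000 5.48505899e+00
100.000000 5.35394997e+00
101.000000 5.22739295e+00
102.000000 5.10518884e+00
103.000000 4.98714906e+00
104.000000 4.87309484e+00
105.000000 4.76285665e+00
106.000000 4.65627365e+00
107.000000 4.55319316e+00
108.000000 4.45347018e+00
109.000000 4.35696693e+00
110.000000 4.26355243e+00
111.000000 4.17310214e+00
112.000000 4.08549753e+00
113.000000 4.00062582e+00
114.000000 3.91837956e+00
115.000000 3.83804235e+00
116.000000 3.76007764e+00
117.000000 3.68451245e+00
118.000000 3.61125341e+00
119.000000 3.54021150e+00
120.000000 3.47130187e+00
121.000000 3.40444358e+00
122.000000 3.33955936e+00
123.000000 3.27657550e+00
124.000000 3.21542156e+00
125.000000 3.15603028e+00
126.000000 3.09833736e+00
127.000000 3.04228133e+00
128.000000 2.98780342e+00
129.000000 2.93484739e+00
130.000000 2.88335940e+00
131.000000 2.83328795e+00
132.000000 2.78458368e+00
133.000000 2.73719932e+00
134.000000 2.69108957e+00
135.000000 2.64621100e+00
136.000000 2.60252198e+00
137.000000 2.55998256e+00
138.000000 2.51855441e+00
139.000000 2.47820076e+00
140.000000 2.43888628e+00
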