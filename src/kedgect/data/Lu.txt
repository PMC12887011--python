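# Total mass attenuation of Lu, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.23339223e+02
16.000000 1.04341637e+02
17.000000 8.91318741e+01
18.000000 7.68005618e+01
19.000000 6.66855051e+01
20.000000 5.83069609e+01
21.000000 5.13053146e+01
22.000000 4.54041143e+01
23.000000 4.03957533e+01
24.000000 3.61173151e+01
25.000000 3.24387602e+01
26.000000 2.92571269e+01
27.000000 2.64868080e+01
28.000000 2.40595102e+01
29.000000 2.19296884e+01
30.000000 2.00524811e+01
31.000000 1.83909853e+01
32.000000 1.69146456e+01
33.000000 1.55980080e+01
34.000000 1.44197461e+01
35.000000 1.33618951e+01
36.000000 1.24092455e+01
37.000000 1.15488588e+01
38.000000 1.07696783e+01
39.000000 1.00622153e+01
40.000000 9.41829397e+00
41.000000 8.82986873e+00
42.000000 8.29195245e+00
43.000000 7.79921808e+00
44.000000 7.34695283e+00
45.000000 6.93091299e+00
46.000000 6.54705581e+00
47.000000 6.19285236e+00
48.000000 5.86431874e+00
49.000000 5.56015541e+00
50.000000 5.27823278e+00
51.000000 5.01652449e+00
52.000000 4.77322359e+00
53.000000 4.54671512e+00
54.000000 4.33555260e+00
55.000000 4.13843781e+00
56.000000 3.95420315e+00
57.000000 3.78179655e+00
58.000000 3.62026828e+00
59.000000 3.46875943e+00
60.000000 3.32649189e+00
61.000000 3.19275957e+00
62.000000 3.06692072e+00
63.000000 2.94839116e+00
63.313800 2.91318216e+00
63.313800 1.30234818e+01
64.000000 1.26882501e+01
65.000000 1.22159023e+01
66.000000 1.17658627e+01
67.000000 1.13295765e+01
68.000000 1.09101330e+01
69.000000 1.05122571e+01
70.000000 1.01345538e+01
71.000000 9.77573596e+00
72.000000 9.43461525e+00
73.000000 9.11009295e+00
74.000000 8.80115223e+00
75.000000 8.50685104e+00
76.000000 8.22631575e+00
77.000000 7.95873531e+00
78.000000 7.70335605e+00
79.000000 7.45947702e+00
80.000000 7.22644560e+00
81.000000 7.00377159e+00
82.000000 6.79058726e+00
83.000000 6.58491033e+00
84.000000 6.38731820e+00
85.000000 6.19804115e+00
86.000000 6.01663946e+00
87.000000 5.84270130e+00
88.000000 5.67584070e+00
89.000000 5.51569566e+00
90.000000 5.36192641e+00
91.000000 5.21421379e+00
92.000000 5.07225787e+00
93.000000 4.93577654e+00
94.000000 4.80450427e+00
95.000000 4.67819104e+00
96.000000 4.55660121e+00
97.000000 4.43951260e+00
98.000000 4.32671559e+00
99.000000 4.21801228e+00
100.000000 4.11321575e+00
101.000000 4.01214931e+00
102.000000 3.91464589e+00
103.000000 3.82054742e+00
104.000000 3.72970422e+00
105.000000 3.64197456e+00
106.000000 3.55722410e+00
107.000000 3.47532547e+00
108.000000 3.39615787e+00
109.000000 3.31960661e+00
110.000000 3.24556283e+00
111.000000 3.17392309e+00
112.000000 3.10458908e+00
113.000000 3.03746733e+00
114.000000 2.97246894e+00
115.000000 2.90950927e+00
116.000000 2.84850779e+00
117.000000 2.78938773e+00
118.000000 2.73207599e+00
119.000000 2.67650287e+00
120.000000 2.62260190e+00
121.000000 2.57030967e+00
122.000000 2.51956564e+00
123.000000 2.47031205e+00
124.000000 2.42249371e+00
125.000000 2.37605788e+00
126.000000 2.33095417e+00
127.000000 2.28671990e+00
128.000000 2.24307842e+00
129.000000 2.20070489e+00
130.000000 2.15955274e+00
131.000000 2.11957745e+00
132.000000 2.08073644e+00
133.000000 2.04298901e+00
134.000000 2.00629619e+00
135.000000 1.97062071e+00
136.000000 1.93592685e+00
137.000000 1.90218042e+00
138.000000 1.86934867e+00
139.000000 1.83740021e+00
140.000000 1.80630492e+00
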