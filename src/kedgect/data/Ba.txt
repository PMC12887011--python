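# Total mass attenuation of Ba, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 6.27568719e+01
16.000000 5.28064214e+01
17.000000 4.48979181e+01
18.000000 3.85277071e+01
19.000000 3.33350607e+01
20.000000 2.90567656e+01
21.000000 2.54976998e+01
22.000000 2.25110174e+01
23.000000 1.99844436e+01
24.000000 1.78315466e+01
25.000000 1.59852729e+01
26.000000 1.43926433e+01
27.000000 1.30072645e+01
28.000000 1.17922569e+01
29.000000 1.07295322e+01
30.000000 9.79562088e+00
31.000000 8.97130633e+00
32.000000 8.24074574e+00
33.000000 7.59079339e+00
34.000000 7.01047570e+00
35.000000 6.49058047e+00
36.000000 6.02333327e+00
37.000000 5.60214032e+00
37.440600 5.43161170e+00
37.440600 2.91259201e+01
38.000000 2.80532124e+01
39.000000 2.62480659e+01
40.000000 2.45868663e+01
41.000000 2.30622951e+01
42.000000 2.16635065e+01
43.000000 2.03776452e+01
44.000000 1.91934155e+01
45.000000 1.81008630e+01
46.000000 1.70911912e+01
47.000000 1.61566062e+01
48.000000 1.52901848e+01
49.000000 1.44854984e+01
50.000000 1.37368808e+01
51.000000 1.30399891e+01
52.000000 1.23903882e+01
53.000000 1.17840952e+01
54.000000 1.12175263e+01
55.000000 1.06874505e+01
56.000000 1.01909496e+01
57.000000 9.72538298e+00
58.000000 9.28835721e+00
59.000000 8.87769937e+00
60.000000 8.49143350e+00
61.000000 8.12775992e+00
62.000000 7.78503709e+00
63.000000 7.46176553e+00
64.000000 7.15657361e+00
65.000000 6.86820491e+00
66.000000 6.59550704e+00
67.000000 6.33742166e+00
68.000000 6.09297564e+00
69.000000 5.86127306e+00
70.000000 5.64148813e+00
71.000000 5.43285889e+00
72.000000 5.23468142e+00
73.000000 5.04630477e+00
74.000000 4.86712632e+00
75.000000 4.69656952e+00
76.000000 4.53404087e+00
77.000000 4.37921898e+00
78.000000 4.23164809e+00
79.000000 4.09090456e+00
80.000000 3.95659434e+00
81.000000 3.82599091e+00
82.000000 3.70137936e+00
83.000000 3.58241575e+00
84.000000 3.46877975e+00
85.000000 3.36017276e+00
86.000000 3.25631615e+00
87.000000 3.15694974e+00
88.000000 3.06183041e+00
89.000000 2.97073077e+00
90.000000 2.88343796e+00
91.000000 2.79975264e+00
92.000000 2.71948794e+00
93.000000 2.64246856e+00
94.000000 2.56852996e+00
95.000000 2.49751757e+00
96.000000 2.42928612e+00
97.000000 2.36369896e+00
98.000000 2.30062747e+00
99.000000 2.23995053e+00
100.000000 2.18155401e+00
101.000000 2.12533026e+00
102.000000 2.07117776e+00
103.000000 2.01900065e+00
104.000000 1.96870837e+00
105.000000 1.92021536e+00
106.000000 1.87344069e+00
107.000000 1.82830782e+00
108.000000 1.78474426e+00
109.000000 1.74268140e+00
110.000000 1.70205417e+00
111.000000 1.66280093e+00
112.000000 1.62486320e+00
113.000000 1.58818547e+00
114.000000 1.55271505e+00
115.000000 1.51840190e+00
116.000000 1.48519845e+00
117.000000 1.45305948e+00
118.000000 1.42194200e+00
119.000000 1.39180508e+00
120.000000 1.36260976e+00
121.000000 1.33431895e+00
122.000000 1.30689731e+00
123.000000 1.28031115e+00
124.000000 1.25452835e+00
125.000000 1.22951827e+00
126.000000 1.20525168e+00
127.000000 1.18170068e+00
128.000000 1.15883862e+00
129.000000 1.13664004e+00
130.000000 1.11508061e+00
131.000000 1.09413708e+00
132.000000 1.07378721e+00
133.000000 1.05400973e+00
134.000000 1.03478428e+00
135.000000 1.01609136e+00
136.000000 9.97912326e-01
137.000000 9.80229296e-01
138.000000 9.63025139e-01
139.000000 9.46283441e-01
140.000000 9.29988459e-01
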