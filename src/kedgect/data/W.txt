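# Total mass attenuation of W, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.37105562e+02
16.000000 1.16128704e+02
17.000000 9.93070462e+01
18.000000 8.56522329e+01
19.000000 7.44439612e+01
20.000000 6.51514684e+01
21.000000 5.73745959e+01
22.000000 5.08150258e+01
23.000000 4.52424715e+01
24.000000 4.04740413e+01
25.000000 3.63699346e+01
26.000000 3.28179736e+01
27.000000 2.97225390e+01
28.000000 2.70070571e+01
29.000000 2.46235698e+01
30.000000 2.25221429e+01
31.000000 2.06616767e+01
32.000000 1.90081226e+01
33.000000 1.75331021e+01
34.000000 1.62128269e+01
35.000000 1.50272498e+01
36.000000 1.39593909e+01
37.000000 1.29947997e+01
38.000000 1.21211231e+01
39.000000 1.13277562e+01
40.000000 1.06055580e+01
41.000000 9.94661954e+00
42.000000 9.34407279e+00
43.000000 8.79193338e+00
44.000000 8.28496962e+00
45.000000 7.81796807e+00
46.000000 7.38749604e+00
47.000000 6.99017184e+00
48.000000 6.62281968e+00
49.000000 6.28262520e+00
50.000000 5.96708808e+00
51.000000 5.67361105e+00
52.000000 5.40064753e+00
53.000000 5.14596537e+00
54.000000 4.90818415e+00
55.000000 4.68622317e+00
56.000000 4.47876750e+00
57.000000 4.28463231e+00
58.000000 4.10274810e+00
59.000000 3.93214765e+00
60.000000 3.77195478e+00
61.000000 3.62137445e+00
62.000000 3.47968409e+00
63.000000 3.34622593e+00
64.000000 3.22040034e+00
65.000000 3.10165984e+00
66.000000 2.98950387e+00
67.000000 2.88347416e+00
68.000000 2.78315055e+00
69.000000 2.68814737e+00
69.525000 2.64072951e+00
69.525000 1.12425687e+01
70.000000 1.10622592e+01
71.000000 1.06900155e+01
72.000000 1.03326896e+01
73.000000 9.98912513e+00
74.000000 9.65235263e+00
75.000000 9.33159016e+00
76.000000 9.02587768e+00
77.000000 8.73432426e+00
78.000000 8.45610243e+00
79.000000 8.19044281e+00
80.000000 7.93662939e+00
81.000000 7.69494040e+00
82.000000 7.46353502e+00
83.000000 7.24186411e+00
84.000000 7.02941368e+00
85.000000 6.82570239e+00
86.000000 6.63027906e+00
87.000000 6.44272048e+00
88.000000 6.26262938e+00
89.000000 6.08963262e+00
90.000000 5.92337943e+00
91.000000 5.76262606e+00
92.000000 5.60755064e+00
93.000000 5.45844564e+00
94.000000 5.31502165e+00
95.000000 5.17700616e+00
96.000000 5.04414236e+00
97.000000 4.91618806e+00
98.000000 4.79291481e+00
99.000000 4.67410690e+00
100.000000 4.55956059e+00
101.000000 4.44908331e+00
102.000000 4.34249295e+00
103.000000 4.23961720e+00
104.000000 4.14029295e+00
105.000000 4.04436568e+00
106.000000 3.95168898e+00
107.000000 3.86212401e+00
108.000000 3.77553907e+00
109.000000 3.69180917e+00
110.000000 3.61081562e+00
111.000000 3.53244566e+00
112.000000 3.45659214e+00
113.000000 3.38315316e+00
114.000000 3.31203179e+00
115.000000 3.24313578e+00
116.000000 3.17637730e+00
117.000000 3.11167269e+00
118.000000 3.04894224e+00
119.000000 2.98810994e+00
120.000000 2.92910333e+00
121.000000 2.87185326e+00
122.000000 2.81629375e+00
123.000000 2.76236179e+00
124.000000 2.70999720e+00
125.000000 2.65914247e+00
126.000000 2.60974266e+00
127.000000 2.56174520e+00
128.000000 2.51509984e+00
129.000000 2.46975847e+00
130.000000 2.42567506e+00
131.000000 2.38280553e+00
132.000000 2.34110767e+00
133.000000 2.30054101e+00
134.000000 2.26106680e+00
135.000000 2.22264787e+00
136.000000 2.18524856e+00
137.000000 2.14883470e+00
138.000000 2.11337345e+00
139.000000 2.07883334e+00
140.000000 2.04439204e+00
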