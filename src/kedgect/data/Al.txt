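# Total mass attenuation of Al, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 7.79114690e+00
16.000000 6.45507942e+00
17.000000 5.41373838e+00
18.000000 4.59026555e+00
19.000000 3.93062180e+00
20.000000 3.39606674e+00
21.000000 2.95834026e+00
22.000000 2.59650162e+00
23.000000 2.29481181e+00
24.000000 2.04128748e+00
25.000000 1.82669630e+00
26.000000 1.64384794e+00
27.000000 1.48704916e+00
28.000000 1.35179524e+00
29.000000 1.23458379e+00
30.000000 1.13250065e+00
31.000000 1.04317780e+00
32.000000 9.64677671e-01
33.000000 8.95404663e-01
34.000000 8.34036858e-01
35.000000 7.79472844e-01
36.000000 7.30790041e-01
37.000000 6.87211767e-01
38.000000 6.48081080e-01
39.000000 6.12839801e-01
40.000000 5.81011662e-01
41.000000 5.52188642e-01
42.000000 5.26019839e-01
43.000000 5.02202379e-01
44.000000 4.80473922e-01
45.000000 4.60606490e-01
46.000000 4.42401334e-01
47.000000 4.25684650e-01
48.000000 4.10304021e-01
49.000000 3.96125398e-01
50.000000 3.83030577e-01
51.000000 3.70915059e-01
52.000000 3.59686232e-01
53.000000 3.49261816e-01
54.000000 3.39568556e-01
55.000000 3.30541082e-01
56.000000 3.22120934e-01
57.000000 3.14255729e-01
58.000000 3.06898435e-01
59.000000 3.00006747e-01
60.000000 2.93542535e-01
61.000000 2.87471379e-01
62.000000 2.81762147e-01
63.000000 2.76386642e-01
64.000000 2.71319279e-01
65.000000 2.66536807e-01
66.000000 2.62018066e-01
67.000000 2.57743769e-01
68.000000 2.53696313e-01
69.000000 2.49859610e-01
70.000000 2.46218935e-01
71.000000 2.42760793e-01
72.000000 2.39472801e-01
73.000000 2.36343587e-01
74.000000 2.33362685e-01
75.000000 2.30520462e-01
76.000000 2.27808035e-01
77.000000 2.25217206e-01
78.000000 2.22740400e-01
79.000000 2.20370613e-01
80.000000 2.18101357e-01
81.000000 2.15926623e-01
82.000000 2.13840833e-01
83.000000 2.11838811e-01
84.000000 2.09915743e-01
85.000000 2.08067152e-01
86.000000 2.06288871e-01
87.000000 2.04577015e-01
88.000000 2.02927961e-01
89.000000 2.01338327e-01
90.000000 1.99804954e-01
91.000000 1.98324887e-01
92.000000 1.96895363e-01
93.000000 1.95513795e-01
94.000000 1.94177755e-01
95.000000 1.92884970e-01
96.000000 1.91633306e-01
97.000000 1.90420757e-01
98.000000 1.89245439e-01
99.000000 1.88105583e-01
100.000000 1.86999520e-01
101.000000 1.85925681e-01
102.000000 1.84882586e-01
103.000000 1.83868841e-01
104.000000 1.82883131e-01
105.000000 1.81924213e-01
106.000000 1.80990915e-01
107.000000 1.80082128e-01
108.000000 1.79196804e-01
109.000000 1.78333951e-01
110.000000 1.77492629e-01
111.000000 1.76671950e-01
112.000000 1.75871070e-01
113.000000 1.75089190e-01
114.000000 1.74325553e-01
115.000000 1.73579437e-01
116.000000 1.72850160e-01
117.000000 1.72137072e-01
118.000000 1.71439556e-01
119.000000 1.70757025e-01
120.000000 1.70088919e-01
121.000000 1.69434708e-01
122.000000 1.68793884e-01
123.000000 1.68165965e-01
124.000000 1.67550491e-01
125.000000 1.66947024e-01
126.000000 1.66355143e-01
127.000000 1.65774451e-01
128.000000 1.65204565e-01
129.000000 1.64645121e-01
130.000000 1.64095770e-01
131.000000 1.63556180e-01
132.000000 1.63026033e-01
133.000000 1.62505022e-01
134.000000 1.61992857e-01
135.000000 1.61489258e-01
136.000000 1.60993957e-01
137.000000 1.60506699e-01
138.000000 1.60027237e-01
139.000000 1.59555336e-01
140.000000 1.59090768e-01
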