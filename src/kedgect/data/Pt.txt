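# Total mass attenuation of Pt, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.56778755e+02
16.000000 1.33046139e+02
17.000000 1.13974410e+02
18.000000 9.84490551e+01
19.000000 8.56809920e+01
20.000000 7.50786042e+01
21.000000 6.61956708e+01
22.000000 5.86928912e+01
23.000000 5.23089421e+01
24.000000 4.68390578e+01
25.000000 4.21250637e+01
26.000000 3.80392737e+01
27.000000 3.44740513e+01
28.000000 3.13432446e+01
29.000000 2.85906199e+01
30.000000 2.61624016e+01
31.000000 2.40115094e+01
32.000000 2.20989085e+01
33.000000 2.03920389e+01
34.000000 1.88635876e+01
35.000000 1.74905209e+01
36.000000 1.62533167e+01
37.000000 1.51353512e+01
38.000000 1.41224049e+01
39.000000 1.32022642e+01
40.000000 1.23643961e+01
41.000000 1.15996831e+01
42.000000 1.09002041e+01
43.000000 1.02590545e+01
44.000000 9.67019577e+00
45.000000 9.12833084e+00
46.000000 8.62879920e+00
47.000000 8.16748888e+00
48.000000 7.74076217e+00
49.000000 7.34539261e+00
50.000000 6.97851152e+00
51.000000 6.63716076e+00
52.000000 6.31950199e+00
53.000000 6.02353002e+00
54.000000 5.74739682e+00
55.000000 5.48944202e+00
56.000000 5.24817090e+00
57.000000 5.02223525e+00
58.000000 4.81030999e+00
59.000000 4.61132087e+00
60.000000 4.42438811e+00
61.000000 4.24822534e+00
62.000000 4.08239151e+00
63.000000 3.92618937e+00
64.000000 3.77891802e+00
65.000000 3.63993751e+00
66.000000 3.50866271e+00
67.000000 3.38455782e+00
68.000000 3.26713157e+00
69.000000 3.15593297e+00
70.000000 3.05054745e+00
71.000000 2.95059342e+00
72.000000 2.85571930e+00
73.000000 2.76560074e+00
74.000000 2.67993816e+00
75.000000 2.59845460e+00
76.000000 2.52089370e+00
77.000000 2.44701794e+00
78.000000 2.37660702e+00
78.394800 2.35005476e+00
78.394800 9.35291904e+00
79.000000 9.17183131e+00
80.000000 8.89165105e+00
81.000000 8.64536260e+00
82.000000 8.40690863e+00
83.000000 8.16388102e+00
84.000000 7.92663523e+00
85.000000 7.69915300e+00
86.000000 7.48092864e+00
87.000000 7.27148794e+00
88.000000 7.07038590e+00
89.000000 6.87720462e+00
90.000000 6.69155142e+00
91.000000 6.51305699e+00
92.000000 6.34137384e+00
93.000000 6.17617476e+00
94.000000 6.01715144e+00
95.000000 5.86401321e+00
96.000000 5.71648586e+00
97.000000 5.57431055e+00
98.000000 5.43724279e+00
99.000000 5.30505155e+00
100.000000 5.17751835e+00
101.000000 5.05443650e+00
102.000000 4.93553209e+00
103.000000 4.81993014e+00
104.000000 4.70831107e+00
105.000000 4.60050167e+00
106.000000 4.49633778e+00
107.000000 4.39566376e+00
108.000000 4.29833196e+00
109.000000 4.20420228e+00
110.000000 4.11314166e+00
111.000000 4.02502372e+00
112.000000 3.93972832e+00
113.000000 3.85714127e+00
114.000000 3.77715391e+00
115.000000 3.69966283e+00
116.000000 3.62456961e+00
117.000000 3.55178045e+00
118.000000 3.48120603e+00
119.000000 3.41276116e+00
120.000000 3.34636461e+00
121.000000 3.28193889e+00
122.000000 3.21941004e+00
123.000000 3.15870742e+00
124.000000 3.09976361e+00
125.000000 3.04251416e+00
126.000000 2.98689745e+00
127.000000 2.93285460e+00
128.000000 2.88032925e+00
129.000000 2.82926751e+00
130.000000 2.77961778e+00
131.000000 2.73133064e+00
132.000000 2.68435878e+00
133.000000 2.63865685e+00
134.000000 2.59418140e+00
135.000000 2.55089077e+00
136.000000 2.50874501e+00
137.000000 2.46770577e+00
138.000000 2.42773628e+00
139.000000 2.38880123e+00
140.000000 2.35086671e+00
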