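# Total mass attenuation of Bi, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 1.15695052e+02
16.000000 1.35459463e+02
17.000000 1.33702118e+02
18.000000 1.15724379e+02
19.000000 1.00890478e+02
20.000000 8.85497319e+01
21.000000 7.81912044e+01
22.000000 6.94287279e+01
23.000000 6.19617318e+01
24.000000 5.55556663e+01
25.000000 5.00260984e+01
26.000000 4.52261486e+01
27.000000 4.10320973e+01
28.000000 3.73440249e+01
29.000000 3.41001507e+01
30.000000 3.12346097e+01
31.000000 2.86930300e+01
32.000000 2.64267389e+01
33.000000 2.43992299e+01
34.000000 2.25795747e+01
35.000000 2.09443063e+01
36.000000 1.94703125e+01
37.000000 1.81379035e+01
38.000000 1.69302310e+01
39.000000 1.58328185e+01
40.000000 1.48331782e+01
41.000000 1.39204977e+01
42.000000 1.30853818e+01
43.000000 1.23196393e+01
44.000000 1.16161053e+01
45.000000 1.09684938e+01
46.000000 1.03712732e+01
47.000000 9.81956224e+00
48.000000 9.30904200e+00
49.000000 8.83588107e+00
50.000000 8.39667217e+00
51.000000 7.98837800e+00
52.000000 7.60828481e+00
53.000000 7.25396269e+00
54.000000 6.92323117e+00
55.000000 6.61412973e+00
56.000000 6.32489208e+00
57.000000 6.05392396e+00
58.000000 5.79978377e+00
59.000000 5.56093887e+00
60.000000 5.33644707e+00
61.000000 5.12526657e+00
62.000000 4.92640906e+00
63.000000 4.73897393e+00
64.000000 4.56213927e+00
65.000000 4.39515386e+00
66.000000 4.23733016e+00
67.000000 4.08803804e+00
68.000000 3.94669920e+00
69.000000 3.81274293e+00
70.000000 3.68572771e+00
71.000000 3.56520564e+00
72.000000 3.45066006e+00
73.000000 3.34183771e+00
74.000000 3.23838064e+00
75.000000 3.13995637e+00
76.000000 3.04625706e+00
77.000000 2.95699744e+00
78.000000 2.87191286e+00
79.000000 2.79075758e+00
80.000000 2.71330320e+00
81.000000 2.63933722e+00
82.000000 2.56866178e+00
83.000000 2.50109247e+00
84.000000 2.43645728e+00
85.000000 2.37459560e+00
86.000000 2.31535741e+00
87.000000 2.25860240e+00
88.000000 2.20419926e+00
89.000000 2.15202502e+00
90.000000 2.10196444e+00
90.525900 2.07668890e+00
90.525900 7.53959150e+00
91.000000 7.44774998e+00
92.000000 7.25727452e+00
93.000000 7.07374794e+00
94.000000 6.89685131e+00
95.000000 6.72628334e+00
96.000000 6.56175923e+00
97.000000 6.40300964e+00
98.000000 6.24977966e+00
99.000000 6.10182796e+00
100.000000 5.95892591e+00
101.000000 5.82085680e+00
102.000000 5.68741515e+00
103.000000 5.55840597e+00
104.000000 5.43309551e+00
105.000000 5.31179785e+00
106.000000 5.19449962e+00
107.000000 5.08103426e+00
108.000000 4.97124356e+00
109.000000 4.86497719e+00
110.000000 4.76209226e+00
111.000000 4.66245282e+00
112.000000 4.56592955e+00
113.000000 4.47239933e+00
114.000000 4.38174490e+00
115.000000 4.29385454e+00
116.000000 4.20862179e+00
117.000000 4.12594510e+00
118.000000 4.04572761e+00
119.000000 3.96787690e+00
120.000000 3.89230474e+00
121.000000 3.81892684e+00
122.000000 3.74766270e+00
123.000000 3.67843537e+00
124.000000 3.61117127e+00
125.000000 3.54580005e+00
126.000000 3.48225439e+00
127.000000 3.42046984e+00
128.000000 3.36038472e+00
129.000000 3.30140946e+00
130.000000 3.24405225e+00
131.000000 3.18826892e+00
132.000000 3.13400469e+00
133.000000 3.08120709e+00
134.000000 3.02982584e+00
135.000000 2.97981272e+00
136.000000 2.93112151e+00
137.000000 2.88370788e+00
138.000000 2.83752927e+00
139.000000 2.79254487e+00
140.000000 2.74871547e+00
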