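# Total mass attenuation of Ca, generated by kedgect.crosssections
# (Cromer-Liberman photoabsorption + Klein-Nishina incoherent with
# IT92 form-factor screening + Thomson coherent; gemmi data tables).
# Duplicated energies mark an absorption edge (below, then above).
# columns: energy_keV  mu_over_rho_cm2_per_g
15.000000 2.94601619e+01
16.000000 2.45077661e+01
17.000000 2.06093881e+01
18.000000 1.74939308e+01
19.000000 1.49763092e+01
20.000000 1.29237468e+01
21.000000 1.12336210e+01
22.000000 9.82933062e+00
23.000000 8.65293232e+00
24.000000 7.66003061e+00
25.000000 6.81621835e+00
26.000000 6.09454842e+00
27.000000 5.47150233e+00
28.000000 4.92856683e+00
29.000000 4.45756113e+00
30.000000 4.04695524e+00
31.000000 3.68736643e+00
32.000000 3.37110699e+00
33.000000 3.09183763e+00
34.000000 2.84429957e+00
35.000000 2.62410568e+00
36.000000 2.42757666e+00
37.000000 2.25161126e+00
38.000000 2.09358320e+00
39.000000 1.95125845e+00
40.000000 1.82272856e+00
41.000000 1.70635671e+00
42.000000 1.60073364e+00
43.000000 1.50464166e+00
44.000000 1.41702489e+00
45.000000 1.33696481e+00
46.000000 1.26365983e+00
47.000000 1.19640831e+00
48.000000 1.13459430e+00
49.000000 1.07767559e+00
50.000000 1.02517364e+00
51.000000 9.76664999e-01
52.000000 9.31774043e-01
53.000000 8.90166810e-01
54.000000 8.51545693e-01
55.000000 8.15644908e-01
56.000000 7.82226600e-01
57.000000 7.51077459e-01
58.000000 7.22005836e-01
59.000000 6.94839204e-01
60.000000 6.69421977e-01
61.000000 6.45613588e-01
62.000000 6.23286843e-01
63.000000 6.02326439e-01
64.000000 5.82627698e-01
65.000000 5.64095442e-01
66.000000 5.46642998e-01
67.000000 5.30191322e-01
68.000000 5.14668234e-01
69.000000 5.00007727e-01
70.000000 4.86149357e-01
71.000000 4.73037715e-01
72.000000 4.60621927e-01
73.000000 4.48855240e-01
74.000000 4.37694636e-01
75.000000 4.27100479e-01
76.000000 4.17036220e-01
77.000000 4.07468114e-01
78.000000 3.98364973e-01
79.000000 3.89697942e-01
80.000000 3.81440300e-01
81.000000 3.73567275e-01
82.000000 3.66055881e-01
83.000000 3.58884772e-01
84.000000 3.52034105e-01
85.000000 3.45485414e-01
86.000000 3.39221508e-01
87.000000 3.33226362e-01
88.000000 3.27485029e-01
89.000000 3.21983556e-01
90.000000 3.16708907e-01
91.000000 3.11648893e-01
92.000000 3.06792111e-01
93.000000 3.02127881e-01
94.000000 2.97646196e-01
95.000000 2.93337674e-01
96.000000 2.89193509e-01
97.000000 2.85205435e-01
98.000000 2.81365682e-01
99.000000 2.77666945e-01
100.000000 2.74102354e-01
101.000000 2.70665438e-01
102.000000 2.67350104e-01
103.000000 2.64150608e-01
104.000000 2.61061531e-01
105.000000 2.58077763e-01
106.000000 2.55194476e-01
107.000000 2.52407110e-01
108.000000 2.49711356e-01
109.000000 2.47103135e-01
110.000000 2.44578593e-01
111.000000 2.42134075e-01
112.000000 2.39766125e-01
113.000000 2.37471463e-01
114.000000 2.35246981e-01
115.000000 2.33089731e-01
116.000000 2.30996915e-01
117.000000 2.28965876e-01
118.000000 2.26994090e-01
119.000000 2.25079160e-01
120.000000 2.23218802e-01
121.000000 2.21410850e-01
122.000000 2.19653239e-01
123.000000 2.17944003e-01
124.000000 2.16281270e-01
125.000000 2.14663258e-01
126.000000 2.13088266e-01
127.000000 2.11554673e-01
128.000000 2.10060934e-01
129.000000 2.08605573e-01
130.000000 2.07187181e-01
131.000000 2.05804412e-01
132.000000 2.04455982e-01
133.000000 2.03140661e-01
134.000000 2.01857277e-01
135.000000 2.00604704e-01
136.000000 1.99381870e-01
137.000000 1.98187744e-01
138.000000 1.97021343e-01
139.000000 1.95881724e-01
140.000000 1.94767983e-01
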