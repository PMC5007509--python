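Allele,D8S1179,D21S11,D7S820,CSF1PO,D3S1358,TH01,D13S317,D16S539,D2S1338,D19S433,vWA,TPOX,D18S51,D5S818,FGA
6,,,,,,0.153,,,,,,,,,
7,,,0.026,,,0.204,,,,,,,,0.005,
8,0.005,,0.189,0.010,,0.107,0.189,0.066,,,,0.469,,,
9,,,0.061,0.046,,0.418,0.133,0.230,,,,0.122,,0.046,
9.1,,,0.005,,,,,,,,,,,,
9.3,,,,,,0.107,,,,,,,,,
10,0.117,,0.158,0.194,,0.010,0.102,0.046,,,0.005,0.082,,0.143,
11,0.071,,0.276,0.250,,,0.245,0.270,,0.010,,0.306,0.031,0.337,
11.2,,,,,,,,,,0.010,,,,,
12,0.112,,0.260,0.434,,,0.276,0.235,,0.036,,0.020,0.046,0.332,
12.2,,,,,,,,,,0.010,,,,,
13,0.168,,0.015,0.061,,,0.046,0.122,,0.256,,,0.158,0.128,
13.2,,,,,,,,,,0.026,,,,,
14,0.179,,0.010,0.005,0.041,,0.010,0.031,,0.316,0.138,,0.199,0.010,
14.2,,,,,,,,,,0.082,,,,,
15,0.255,,,,0.321,,,,0.005,0.092,0.082,,0.214,,
15.2,,,,,,,,,,0.092,,,,,
16,0.082,,,,0.265,,,,0.056,0.041,0.230,,0.087,,
16.2,,,,,,,,,,0.010,,,,,
17,0.005,,,,0.245,,,,0.133,,0.230,,0.066,,
17.2,,,,,,,,,0.189,0.010,,,,,
18,0.005,,,,0.117,,,,0.077,,0.199,,0.036,,0.005
19,,,,,0.005,,,,,,0.102,,0.087,,0.128
20,,,,,0.005,,,,0.005,,0.015,,0.041,,0.071
20.2,,,,,,,,,0.071,,,,,,0.005
21,,,,,,,,,,,,,0.015,,0.107
22,,,,,,,,,0.138,,,,,,0.138
22.2,,,,,,,,,,,,,,,0.010
23,,,,,,,,,0.199,,,,0.005,,0.153
23.2,,,,,,,,,,,,,,,0.005
24,,,,,,,,,0.097,,,,0.010,,0.153
24.2,,,,,,,,,0.031,,,,,,0.005
25,,,,,,,,,,,,,0.005,,0.138
26,,,,,,,,,,,,,,,0.046
27,,,,,,,,,,,,,,,0.026
28,,0.133,,,,,,,,,,,,,0.005
29,,0.214,,,,,,,,,,,,,0.005
29.2,,0.010,,,,,,,,,,,,,
30,,0.230,,,,,,,,,,,,,
30.2,,0.036,,,,,,,,,,,,,
31,,0.082,,,,,,,,,,,,,
31.2,,0.107,,,,,,,,,,,,,
32,,0.005,,,,,,,,,,,,,
32.2,,0.122,,,,,,,,,,,,,
33.2,,0.046,,,,,,,,,,,,,
34.2,,0.015,,,,,,,,,,,,,
n,98,98,98,98,98,98,98,98,98,98,98,98,98,98,98
PD,0.944,0.950,0.918,0.863,0.888,0.887,0.923,0.927,0.960,0.924,0.931,0.843,0.957,0.885,0.963
PIC,0.820,0.830,0.760,0.660,0.710,0.700,0.770,0.770,0.850,0.780,0.790,0.610,0.850,0.690,0.870
PE,0.649,0.770,0.573,0.467,0.519,0.536,0.591,0.649,0.630,0.770,0.649,0.293,0.729,0.374,0.689
PI,2.880,4.450,2.330,1.810,2.040,2.130,2.450,2.880,2.720,4.450,2.880,1.260,3.770,1.480,3.270
Hobs,0.827,0.857,0.786,0.724,0.755,0.663,0.796,0.827,0.816,0.827,0.827,0.602,0.867,0.663,0.847
Hexp,0.841,0.812,0.794,0.709,0.755,0.651,0.802,0.801,0.868,0.722,0.823,0.667,0.868,0.742,0.877
p_value,0.058,0.779,0.680,0.504,0.412,0.707,0.162,0.970,0.186,0.074,0.117,0.736,0.059,0.057,0.153
Pm,0.056,0.050,0.082,0.137,0.112,0.113,0.077,0.073,0.040,0.076,0.069,0.157,0.043,0.115,0.037
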