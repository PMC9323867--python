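rec,qs_pct,ds_pct,di_pct
1,12.02,51.46,36.52
2,35.23,49.81,14.96
3,12.14,81.02,6.84
4,42.05,47.10,10.85
5,48.26,41.38,10.36
6,10.15,72.20,17.65
7,62.73,32.11,5.16
8,58.72,36.49,4.79
9,44.06,45.47,10.47
10,2.30,84.54,13.16
11,6.69,7.23,86.08
12,24.62,56.64,18.74
13,0.02,82.63,17.35
14,44.02,48.89,7.09
15,0,60.32,39.68
16,26.58,62.37,11.05
17,0,19.48,80.52
18,58.62,37.71,3.67
19,71.82,24.86,3.32
20,4.26,70.11,25.63
21,65.16,30.89,3.95
22,49.38,45.14,5.48
23,90.42,8.92,0.66
24,71.37,27.34,1.29
25,93.64,5.43,0.93
26,79.78,19.66,0.56
27,81.31,17.99,0.70
28,68.34,30.61,1.05
29,73.18,25.99,0.82
30,79.03,20.08,0.89
31,81.28,18.13,0.59
32,68.44,30.76,0.80
33,92.63,6.94,0.43
34,91.23,8.34,0.43
35,77.15,22.40,0.45
36,74.65,24.63,0.72
37,84.57,14.87,0.56
38,77.02,22.19,0.79
39,68.61,30.76,0.63
40,69.66,29.31,1.03
41,82.21,17.14,0.65
42,92.58,6.87,0.55
43,50.16,48.39,1.45
44,76.13,23.27,0.60
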