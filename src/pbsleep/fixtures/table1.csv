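rec,subject,dataset,st_h,se,tne,ahi,timetable,uncertain
1,S1,apnea,6.01,0.72,21,3.49,,1
2,S2,apnea,9.66,0.77,145,15.01,,0
3,S3,apnea,8.98,0.95,368,40.99,,1
4,S4,apnea,8.74,0.42,2,0.23,,0
5,S5,apnea,7.64,0.44,1,0.13,,0
6,S6,apnea,8.87,0.66,454,50.63,,0
7,S7,apnea,7.22,0.63,13,1.80,,0
8,S8,apnea,8.34,0.59,6,0.72,,0
9,S9,apnea,9.65,0.68,5,0.52,,0
10,S10,apnea,6.18,0.46,196,31.74,,0
11,S11,apnea,6.61,0.61,345,52.21,,0
12,S12,apnea,6.49,0.53,180,27.75,,0
13,S13,apnea,7.69,0.58,99,12.87,,1
14,S14,apnea,9.05,0.68,162,17.90,,0
15,S15,apnea,7.32,0.63,161,22.00,,1
16,S16,apnea,11.17,0.64,109,9.76,,0
17,S17,apnea,6.79,0.38,319,46.97,,0
18,S18,apnea,8.56,0.90,39,4.56,,0
19,S19,apnea,8.18,0.87,27,3.30,,0
20,S20,apnea,7.02,0.77,161,22.92,,0
21,S21,apnea,8.40,0.91,1,0.12,,0
22,S22,apnea,5.73,0.80,34,5.93,,0
23,S23,shift_work,4.34,0.95,,,D,0
24,S23,shift_work,9.00,0.83,,,N,0
25,S24,shift_work,3.90,0.84,,,D,0
26,S24,shift_work,9.83,0.85,,,N,0
27,S25,shift_work,4.94,0.85,,,D,0
28,S25,shift_work,8.36,0.69,,,N,0
29,S26,shift_work,4.06,0.69,,,D,0
30,S26,shift_work,8.37,0.89,,,N,0
31,S27,shift_work,4.89,0.86,,,D,0
32,S27,shift_work,9.05,0.83,,,N,0
33,S28,shift_work,5.54,0.94,,,D,0
34,S28,shift_work,8.46,0.95,,,N,0
35,S29,shift_work,5.25,0.93,,,D,0
36,S29,shift_work,8.68,0.75,,,N,0
37,S30,shift_work,4.13,0.93,,,D,0
38,S30,shift_work,8.09,0.90,,,N,0
39,S31,shift_work,4.60,0.86,,,D,0
40,S31,shift_work,9.23,0.85,,,N,0
41,S32,shift_work,4.80,0.79,,,D,0
42,S32,shift_work,7.86,0.92,,,N,0
43,S33,shift_work,5.21,0.47,,,D,0
44,S33,shift_work,9.52,0.71,,,N,0
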