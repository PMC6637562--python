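spot_id,protein,pr_dfd_mean,pr_dfd_se,pr_dfd_cl,pr_dfd_cu,pr_c_mean,pr_c_se,pr_c_cl,pr_c_cu,fc_printed,rc_printed
1,PGM1 (1),0.41,0.10,0.292,0.603,0,,,,+inf,0.44
5,PGM1 (2),0.08,0.03,0.051,0.108,0.36,0.12,0.169,0.696,-4.50,-0.30
6,UQCRC1,0,,,,0.12,0.06,0.060,0.171,-inf,-0.13
7,ENO3 (1),0.54,0.21,0.206,0.939,0,,,,+inf,0.57
8,ENO3 (2),0.48,0.08,0.281,0.614,0,,,,+inf,0.51
9,ENO3 (3),0.36,0.10,0.153,0.630,0,,,,+inf,0.38
10,ACTA1 (1),0.33,0.06,0.205,0.435,0,,,,+inf,0.35
11,ACTA1 (2),0.31,0.03,0.238,0.371,0,,,,+inf,0.33
15,CKM (1),0.35,0.16,0.154,0.655,0,,,,+inf,0.37
16,CKM (2),0.31,0.04,0.237,0.379,0,,,,+inf,0.32
18,ACTA1 (3),0,,,,0.12,0.04,0.067,0.186,-inf,-0.13
19,ACTA1 (4),0,,,,0.15,0.05,0.041,0.206,-inf,-0.16
20,ACTA1 (5),0,,,,0.13,0.02,0.105,0.179,-inf,-0.14
21,ACTA1 (6),0,,,,0.11,0.05,0.031,0.187,-inf,-0.12
22,TNNT3 (1),0.70,0.12,0.458,0.948,0,,,,+inf,0.74
23,TNNT3 (2),0.69,0.08,0.505,0.874,0,,,,+inf,0.73
24,TNNT3 (3),0.66,0.10,0.452,0.804,0,,,,+inf,0.70
25,TNNT3 (4),0.63,0.06,0.447,0.693,0,,,,+inf,0.67
26,CAPZA2,0.72,0.19,0.531,0.904,0,,,,+inf,0.77
27,ACTA1 (7),0,,,,0.37,0.19,0.175,0.563,-inf,-0.39
30,TNNT1 (1),0,,,,0.73,0.19,0.358,0.929,-inf,-0.78
30A,TNNT1 (2),0.71,0.15,0.402,0.879,0,,,,+inf,0.76
33,HSPB1 (1),0,,,,0.49,0.24,0.033,0.839,-inf,-0.52
34,HSPB1 (2),0.69,0.25,0.192,0.951,0,,,,+inf,0.73
37,HSPB1 (3),0.65,0.19,0.467,0.835,0,,,,+inf,0.69
44,MYL6B (1),0,,,,0.46,0.20,0.087,0.776,-inf,-0.49
46,MYL6B (2),0,,,,0.13,0.03,0.073,0.177,-inf,-0.14
50,HSPB6,0,,,,0.09,0.05,0.011,0.194,-inf,-0.10
51,MYL2 (1),0,,,,0.38,0.14,0.211,0.664,-inf,-0.40
52,MYL2 (2),0,,,,0.37,0.19,0.020,0.764,-inf,-0.39
53,MYLPF (1),0.93,0.05,0.831,1.000,0,,,,+inf,0.99
54,MYLPF (2),0.94,0.04,0.875,1.000,0,,,,+inf,1.00
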