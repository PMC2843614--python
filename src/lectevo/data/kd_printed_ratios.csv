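glycan,ConI|ratio to Con-anc,ConI|ratio to ConI,ConII|ratio to Con-anc,ConII|ratio to ConI,Con-anc|ratio to Con-anc,Con-anc|ratio to ConI,Con-anc-N/C|ratio to Con-anc,Con-anc-N/C|ratio to ConI,Con-anc-L5|ratio to Con-anc,Con-anc-L5|ratio to ConI,Con-anc-N/C/L5|ratio to Con-anc,Con-anc-N/C/L5|ratio to ConI,Con-anc-N/C/L5/L6|ratio to Con-anc,Con-anc-N/C/L5/L6|ratio to ConI,Con-anc-N/C/L5/L6/L3|ratio to Con-anc,Con-anc-N/C/L5/L6/L3|ratio to ConI
01,10,1,1.4,0.13,1,0.10,0.41,0.04,1.6,0.16,3.1,0.30,5.0,0.47,7.4,0.71
02,7,1,1.0,0.15,1,0.15,0.34,0.05,1.2,0.18,1.9,0.29,3.1,0.46,4.9,0.73
03,7,1,1.1,0.17,1,0.15,0.33,0.05,1.2,0.18,2.1,0.31,2.9,0.44,4.1,0.62
04,7,1,1.1,0.16,1,0.15,0.33,0.05,1.3,0.19,2.0,0.29,3.3,0.48,5.1,0.74
05,8,1,1.1,0.14,1,0.13,0.32,0.04,1.4,0.18,2.3,0.29,3.9,0.50,5.7,0.73
06,8,1,1.2,0.15,1,0.13,0.35,0.04,1.6,0.20,2.2,0.28,3.6,0.46,5.5,0.70
09,9,1,1.2,0.13,1,0.11,0.34,0.04,1.6,0.17,2.4,0.26,3.9,0.43,6.4,0.69
10,6,1,1.1,0.17,1,0.16,0.33,0.05,1.3,0.20,2.0,0.31,3.1,0.48,4.4,0.68
11,7,1,1.1,0.16,1,0.15,0.34,0.05,1.3,0.19,1.9,0.28,2.9,0.44,4.8,0.72
21,10,1,1.3,0.13,1,0.10,0.39,0.04,1.9,0.18,2.9,0.28,5.0,0.49,7.5,0.73
22,11,1,1.3,0.12,1,0.09,0.32,0.03,1.9,0.18,3.5,0.32,5.4,0.51,7.6,0.71
23,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
41,8,1,0.8,0.10,1,0.12,0.34,0.04,2.2,0.28,3.5,0.43,5.9,0.73,7.7,0.96
42,8,1,1.0,0.12,1,0.12,0.40,0.05,2.0,0.24,3.5,0.42,4.9,0.59,6.4,0.76
43,6,1,0.8,0.14,1,0.18,0.36,0.06,1.4,0.26,2.4,0.42,3.7,0.66,5.5,0.99
26,4,1,1.0,0.25,1,0.26,0.39,0.10,1.5,0.37,2.2,0.55,4.3,1.1,5.5,1.42
27,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
28,17,1,1.8,0.11,1,0.06,0.41,0.02,2.2,0.13,4.2,0.25,7.6,0.46,8.8,0.53
29,-,-,4.7,-,1,-,0.73,-,1.4,-,1.1,-,-,-,-,-
30,-,-,3.0,-,1,-,0.54,-,1.0,-,0.3,-,-,-,-,-
31,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
32,8,1,2.0,0.25,1,0.12,0.50,0.06,1.7,0.21,2.6,0.32,3.1,0.38,5.6,0.68
33,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
34,8,1,1.9,0.26,1,0.13,0.47,0.06,1.8,0.24,2.8,0.37,3.7,0.48,5.7,0.75
38,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
39,24,1,1.7,0.07,1,0.04,0.47,0.02,2.8,0.12,6.7,0.28,14,0.58,15,0.64
40,-,-,0.8,-,1,-,-,-,-,-,-,-,-,-,0.27,-
44,13,1,2.3,0.18,1,0.08,0.44,0.04,14,1.14,32,2.6,39,3.1,19,1.49
45,13,1,1.4,0.11,1,0.08,0.31,0.02,7.3,0.55,15,1.1,24,1.8,11,0.87
46,5,1,1.2,0.26,1,0.21,0.24,0.05,9.8,2.10,21,4.5,24,5.1,7.3,1.57
47,9,1,0.8,0.09,1,0.11,0.30,0.03,2.7,0.31,6.1,0.69,8.3,0.94,11,1.30
48,3,1,1.3,0.40,1,0.30,0.34,0.10,9.9,2.99,22,6.6,22,6.7,6.9,2.08
49,6,1,1.4,0.23,1,0.16,0.39,0.06,1.7,0.27,3.3,0.53,5.9,0.95,7.2,1.16
50,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-,-
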