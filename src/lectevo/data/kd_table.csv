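glycan,ConI,ConII,Con-anc,Con-anc-N/C,Con-anc-L5,Con-anc-N/C/L5,Con-anc-N/C/L5/L6,Con-anc-N/C/L5/L6/L3
01,0.50,3.8,5.2,13,3.2,1.7,1.0,0.70
02,0.36,2.3,2.4,7.1,2.0,1.2,0.77,0.49
03,0.24,1.4,1.6,4.9,1.3,0.78,0.55,0.39
04,0.36,2.3,2.5,7.6,1.9,1.3,0.75,0.49
05,0.58,4.0,4.6,14,3.2,2.0,1.2,0.80
06,0.51,3.4,4.0,12,2.6,1.8,1.1,0.73
09,0.51,3.8,4.7,14,3.0,1.9,1.2,0.74
10,0.42,2.5,2.7,8.0,2.0,1.3,0.86,0.61
11,0.37,2.3,2.5,7.3,2.0,1.3,0.85,0.51
21,1.2,9.6,13,33,6.7,4.4,2.5,1.7
22,1.4,12,15,46,7.8,4.2,2.7,1.9
23,-,-,-,-,-,-,-,-
41,0.96,9.4,7.7,23,3.5,2.2,1.3,1.0
42,0.31,2.5,2.6,6.5,1.3,0.74,0.52,0.40
43,0.35,2.5,2.0,5.5,1.4,0.83,0.53,0.35
26,6.8,28,27,69,18,12,6.2,4.8
27,-,-,-,-,-,-,-,-
28,2.8,26,46,112,20,11,6.1,5.2
29,-,51,242,332,168,215,-,-
30,-,66,196,364,190,696,-,-
31,-,-,-,-,-,-,-,-
32,4.5,18,37,74,22,14,12,7
33,-,-,-,-,-,-,-,-
34,6.4,25,49,104,27,17,13,9
38,-,-,-,-,-,-,-,-
39,2.3,31,54,116,20,8.1,3.9,4
40,-,75,63,178,136,94,28,238
44,4.4,24,55,126,3.9,1.7,1.4,3.0
45,13,122,171,550,24,12,7.1,15
46,9.4,37,44,183,4.5,2.1,1.8,6.0
47,3.8,43,34,115,12,5.6,4.1,3.0
48,17,42,56,166,5.6,2.5,2.5,8.1
49,10,44,62,158,37,19,11,8.7
50,-,-,-,-,-,-,-,-
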