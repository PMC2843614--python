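glycan,ConI,ConII,Con-anc,Con-anc-N/C,Con-anc-L5,Con-anc-N/C/L5,Con-anc-N/C/L5/L6,Con-anc-N/C/L5/L6/L3
01,False,False,False,False,False,False,False,False
02,False,False,False,False,False,False,False,False
03,False,False,False,False,False,False,False,False
04,False,False,False,False,False,False,False,False
05,False,False,False,False,False,False,False,False
06,False,False,False,False,False,False,False,False
09,False,False,False,False,False,False,False,False
10,False,False,False,False,False,False,False,False
11,False,False,False,False,False,False,False,False
21,False,False,False,False,False,False,False,False
22,False,False,False,False,False,False,False,False
23,False,False,False,False,False,False,False,False
41,False,False,False,False,False,False,False,False
42,False,False,False,False,False,False,False,False
43,False,False,False,False,False,False,False,False
26,False,False,False,False,False,False,False,False
27,False,False,False,False,False,False,False,False
28,False,False,False,False,False,False,False,False
29,False,False,False,False,False,False,False,False
30,False,False,False,False,False,False,False,False
31,False,False,False,False,False,False,False,False
32,False,False,False,False,False,False,False,False
33,False,False,False,False,False,False,False,False
34,False,False,False,False,False,False,False,False
38,False,False,False,False,False,False,False,False
39,False,False,False,False,False,False,False,False
40,False,False,False,True,True,True,True,False
44,False,False,False,False,False,False,False,False
45,False,False,False,False,False,False,False,False
46,False,False,False,False,False,False,False,False
47,False,False,False,False,False,False,False,False
48,False,False,False,False,False,False,False,False
49,False,False,False,False,False,False,False,False
50,False,False,False,False,False,False,False,False
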