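rank	gene	cv
1	LINC02593	0.058
2	PDLIM3	0.083
3	RAP1GAP	0.090
4	ACOX2	0.091
5	B4GALT1	0.094
6	TMPRSS3	0.096
7	MATN2	0.098
8	SUSD3	0.099
9	FDFT1	0.099
10	ZNF521	0.099
11	FRY	0.104
12	BARX2	0.107
13	IL20	0.108
14	CTSD	0.118
15	CSTA	0.124
16	DOK7	0.125
17	CYP1A1	0.125
18	LOXL2	0.126
19	RAPGEFL1	0.126
20	PKIB	0.126
21	CCDC68	0.126
22	GATA4	0.128
23	SPOCD1	0.129
24	CRISP3	0.134
25	IGSF1	0.134
26	RAB26	0.136
27	EGR3	0.139
28	SRGAP3	0.139
29	SYNE1	0.143
30	INSYN1	0.145
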