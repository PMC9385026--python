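gene	q_minus	q_plus	sn_ratio	reported_subtype
EGR3	0	279	1.1	ERalpha/beta
ACOX2	0	0	1.4	ERbeta
GATA4	133	2133	1.2	ERalpha/beta
SUSD3	449	3026	0.7	ERalpha
IL20	1307	3091	1.1	ERalpha/beta
ZNF521	0	0	0.9	other
PDLIM3	0	72	1.1	ERalpha/beta
IGSF1	0	0	1.0	other
RAPGEFL1	764	4529	0.0	ERalpha
LOXL2	0	0	8.2	ERbeta
CTSD	234	1683	4.4	ERalpha/beta
TMPRSS3	263	2761	3.2	ERalpha/beta
FDFT1	1121	3753	1.2	ERalpha/beta
PKIB	304	1887	0.8	ERalpha
INSYN1	200	3575	1.0	ERalpha
DOK7	676	2677	32.7	ERalpha/beta
SPOCD1	0	31	1.0	ERalpha
B4GALT1	145	1105	18.9	ERalpha/beta
BARX2	89	465	1.0	ERalpha
SYNE1	0	395	1.0	ERalpha
RAB26	118	991	4.8	ERalpha/beta
RAP1GAP	45	133	2.1	ERalpha/beta
CRISP3	0	0	0.8	other
MATN2	0	200	2.5	ERalpha/beta
CYP1A1	1203	2489	12.3	ERalpha/beta
CCDC68	0	1490	1.2	ERalpha/beta
SRGAP3	125	1290	0.9	ERalpha
CSTA	124	840	1.0	ERalpha
FRY	0	117	0.7	ERalpha
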