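case_id	pathology_dx	grade	cytology	cea_ng_ml	amylase_u_l	cyst_size_mm	mural_nodule	viscosity	eus_impression	genes_tested	algorithm_label	molecular_label
1	IPMN	LG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
2	IPMN	LG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
3	IPMN	LG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
4	IPMN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
5	IPMN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
6	IPMN	LG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
7	IPMN	LG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
8	IPMN	LG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
9	IPMN	LG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
10	IPMN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
11	IPMN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
12	IPMN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
13	IPMN	MG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
14	IPMN	MG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
15	IPMN	MG	POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
16	IPMN	MG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
17	IPMN	MG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
18	IPMN	HG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
19	IPMN	HG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
20	MCN	LG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
21	MCN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
22	MCN	LG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
23	MCN	LG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
24	MCN	LG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
25	MCN	MG	A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
26	MCN	MG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
27	MCN	MG	NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
28	MCN	MG	ND							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
29	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
30	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
31	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
32	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
33	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
34	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
35	PDA		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
36	PDA		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
37	SCA		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
38	SCA		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	nmPCL	nmPCL
39	PNET		A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
40	PNET		POS							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
41	PNET		A/S							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	nmPCL
42	PSEUDOCYST		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	nmPCL	nmPCL
43	PSEUDOCYST		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	nmPCL	nmPCL
44	PSEUDOCYST		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	mPCN	mPCN
45	PSEUDOCYST		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	nmPCL	nmPCL
46	PSEUDOCYST		NEG							APC;ATM;BRAF;CDKN2A;GNAS;KRAS;PIK3CA;PTEN;RB1;SMAD4;TP53;VHL	nmPCL	nmPCL
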