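case_id	gene	protein_change	maf_percent	read_depth	assay	somatic_status
1	KRAS	p.G12V			NGS	cosmic_confirmed
2	KRAS	p.G12V			NGS	cosmic_confirmed
2	GNAS	p.R201C			NGS	cosmic_confirmed
3	KRAS	p.G12V			NGS	cosmic_confirmed
3	GNAS	p.R201C			NGS	cosmic_confirmed
4	KRAS	p.G12V			NGS	cosmic_confirmed
4	GNAS	p.R201H			NGS	cosmic_confirmed
5	KRAS	p.G12V			NGS	cosmic_confirmed
6	KRAS	p.G12R			NGS	cosmic_confirmed
7	KRAS	p.G12R			NGS	cosmic_confirmed
7	GNAS	p.R201H			NGS	cosmic_confirmed
8	KRAS	p.G12A			NGS	cosmic_confirmed
8	GNAS	p.R201H			NGS	cosmic_confirmed
9	KRAS	p.G12R			NGS	cosmic_confirmed
11	KRAS	p.G12V			NGS	cosmic_confirmed
11	GNAS	p.R201C			NGS	cosmic_confirmed
12	KRAS	p.Q61H			NGS	cosmic_confirmed
12	GNAS	p.R201H			NGS	cosmic_confirmed
13	KRAS	p.G12D			NGS	cosmic_confirmed
14	KRAS	p.G12D			NGS	cosmic_confirmed
14	GNAS	p.R201C			NGS	cosmic_confirmed
14	APC	p.?			NGS	cosmic_confirmed
15	KRAS	p.G12V			NGS	cosmic_confirmed
15	GNAS	p.R201C			NGS	cosmic_confirmed
15	CDKN2A	p.?			NGS	cosmic_confirmed
16	KRAS	p.G12A			NGS	cosmic_confirmed
16	KRAS	p.G12T			NGS	cosmic_confirmed
16	GNAS	p.R201C			NGS	cosmic_confirmed
16	GNAS	p.R201H			NGS	cosmic_confirmed
17	GNAS	p.R201C			NGS	cosmic_confirmed
18	KRAS	p.G12V			NGS	cosmic_confirmed
18	TP53	p.?			NGS	cosmic_confirmed
18	PIK3CA	p.?			NGS	cosmic_confirmed
19	BRAF	p.?			NGS	cosmic_confirmed
20	KRAS	p.Q61H			NGS	cosmic_confirmed
22	KRAS	p.G12D			NGS	cosmic_confirmed
23	KRAS	p.G12D			NGS	cosmic_confirmed
25	KRAS	p.G12D			NGS	cosmic_confirmed
25	TP53	p.?			NGS	cosmic_confirmed
26	KRAS	p.G12V			NGS	cosmic_confirmed
28	KRAS	p.G12D			NGS	cosmic_confirmed
29	KRAS	p.G12R			NGS	cosmic_confirmed
29	TP53	p.?			NGS	cosmic_confirmed
30	KRAS	p.G12V			NGS	cosmic_confirmed
30	TP53	p.?			NGS	cosmic_confirmed
30	SMAD4	p.?			NGS	cosmic_confirmed
31	KRAS	p.G12D			NGS	cosmic_confirmed
31	SMAD4	p.?			NGS	cosmic_confirmed
32	KRAS	p.G12D			NGS	cosmic_confirmed
32	RB1	p.?			NGS	cosmic_confirmed
32	SMAD4	p.?			NGS	cosmic_confirmed
32	PTEN	p.?			NGS	cosmic_confirmed
33	KRAS	p.G12D			NGS	cosmic_confirmed
33	TP53	p.?			NGS	cosmic_confirmed
34	GNAS	p.R201H			NGS	cosmic_confirmed
34	SMAD4	p.?			NGS	cosmic_confirmed
34	TP53	p.?			NGS	cosmic_confirmed
35	KRAS	p.Q61C			NGS	cosmic_confirmed
35	GNAS	p.R201C			NGS	cosmic_confirmed
35	TP53	p.?			NGS	cosmic_confirmed
35	CDKN2A	p.?			NGS	cosmic_confirmed
36	KRAS	p.G12D			NGS	cosmic_confirmed
36	GNAS	p.R201H			NGS	cosmic_confirmed
37	VHL	p.?			NGS	cosmic_confirmed
38	VHL	p.?			NGS	cosmic_confirmed
40	ATM	p.?			NGS	cosmic_confirmed
44	KRAS	p.G12D			NGS	cosmic_confirmed
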