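rank	probe_set_id	gene_symbol	emt_class
1	37892_at	COL11A1	other
2	203083_at	THBS2	other
3	217428_s_at	COL10A1	other
4	221729_at	COL5A2	core_overlap
5	210511_s_at	INHBA	reported_additional
6	213909_at	LRRC15	other
7	212488_at	COL5A1	other
8	204619_s_at	VCAN	other
9	209955_s_at	FAP	core_overlap
10	202311_s_at	COL1A1	other
11	203878_s_at	MMP11	other
12	210809_s_at	POSTN	core_overlap
13	202404_s_at	COL1A2	core_overlap
14	202952_s_at	ADAM12	other
15	215076_s_at	COL3A1	core_overlap
16	215446_s_at	LOX	other
17	210495_x_at	FN1	obvious_marker
18	201792_at	AEBP1	other
19	212353_at	SULF1	other
20	202766_s_at	FBN1	core_overlap
21	219087_at	ASPN	other
22	200665_s_at	SPARC	reported_additional
23	202450_s_at	CTSK	other
24	206026_s_at	TNFAIP6	core_overlap
25	222020_s_at	HNT	other
26	206439_at	EPYC	other
27	201069_at	MMP2	core_overlap
28	205479_s_at	PLAU	other
29	218469_at	GREM1	core_overlap
30	201261_x_at	BGN	core_overlap
31	213125_at	OLFML2B	other
32	201744_s_at	LUM	other
33	202998_s_at	LOXL2	other
34	201438_at	COL6A3	other
35	209596_at	MXRA5	other
36	213764_s_at	MFAP5	other
37	204589_at	NUAK1	other
38	217762_s_at	RAB31	other
39	201150_s_at	TIMP3	other
40	221541_at	CRISPLD2	other
41	205422_s_at	ITGBL1	other
42	207173_x_at	CDH11	core_overlap
43	213338_at	TMEM158	other
44	202363_at	SPOCK1	core_overlap
45	204051_s_at	SFRP4	other
46	202283_at	SERPINF1	other
47	209335_at	DCN	core_overlap
48	219655_at	C7orf10	other
49	219561_at	COPZ2	core_overlap
50	219773_at	NOX4	other
51	204464_s_at	EDNRA	other
52	200974_at	ACTA2	obvious_marker
53	202273_at	PDGFRB	reported_additional
54	61734_at	RCN3	other
55	213139_at	SNAI2	obvious_marker
56	220988_s_at	C1QTNF3	other
57	205713_s_at	COMP	other
58	201105_at	LGALS1	other
59	213869_x_at	THY1	core_overlap
60	202465_at	PCOLCE	core_overlap
61	209156_s_at	COL6A2	reported_additional
62	221447_s_at	GLT8D2	other
63	204114_at	NID2	other
64	205991_s_at	PRRX1	core_overlap
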