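family	gene	chrom	pos	ref	alt	consequence	hgvs_c	hgvs_p	dbsnp	maf_shgpdb	maf_1000g	maf_exac	maf_kaviar	cadd_phred	predictsnp2_label	predictsnp2_accuracy	fathmm_mkl	pli	mis_z	genotypes
F1	ACIN1	14	1000000	G	T	missense	c.214G>T	p.(Asp72Tyr)		0.000420345	0			23.5	Neutral	63	0.85074	1.00	2.98	F1_UM=HET;F1_UF=HOM;F1_P=HET;F1_AS1=HOM;F1_AS2=HOM;F1_AS3=HOM;F1_US1=HOM;F1_US2=HOM
F1	LRRK1	15	2000000	A	G	splice_site	c.2687-2A>G			0	0			33	Deleterious	63	0.98391	0.0	3.12	F1_UM=HET;F1_UF=HET;F1_P=HOM;F1_AS1=HOM;F1_AS2=HET;F1_AS3=HOM;F1_US1=HET;F1_US2=HET
F5	DIAPH3	13	3000000	G	A	missense	c.2881G>A	p.(Glu961Lys)		0.004203447	0	3.39E-05	2.59E-05	21.3	Neutral	63	0.90278	0.0	-0.42	F5_UM=WT;F5_UF=HET;F5_P=HET;F5_US1=HET;F5_US2=HET
F5	LIMCH1	4	4000000	G	A	missense	c.1174G>A	p.(Gly392Arg)		0.005884826	0	0.0001	7.76E-05	25.3	Deleterious	87	0.99105	1.00	-0.11	F5_UM=HET;F5_UF=HET;F5_P=HET;F5_US1=HET;F5_US2=HET
F5	LIMCH1	4	5000000	C	T	missense	c.1942C>T	p.(Arg648Cys)		0.001261034	0	1.30E-05	6.50E-06	34	Deleterious	82	0.85122	1.00	-0.11	F5_UM=HET;F5_UF=WT;F5_P=HET;F5_US1=HET;F5_US2=WT
F5	NEK4	3	6000000	C	T	missense	c.671C>T	p.(Ser224Phe)		0.002101723	0			21.1	Deleterious	87	0.93070	0.0	-0.19	F5_UM=HET;F5_UF=WT;F5_P=HET;F5_US1=WT;F5_US2=WT
F7	PCLO	7	7000000	T	C	missense	c.10918T>C	p.(Phe3640Leu)		0.000420345	0			28.2	Deleterious	82	0.98562	1.00	-4.32	F7_UM=HET;F7_UF=HET;F7_P=HOM;F7_AS1=WT
F7	ACCS	11	8000000	G	A	missense	c.1370G>A	p.(Arg457His)		0.002101723	0	1.65E-05	1.29E-05	26.8	Deleterious	87	0.97866	0.0	-0.64	F7_UM=WT;F7_UF=HET;F7_P=HET;F7_AS1=WT
F10	CRELD2	22	9000000	G	A	missense	c.295G>A	p.(Glu99Lys)		0.000420345	0	2.01E-05	1.29E-05	27.5	Deleterious	87	0.97981	0.0	-0.01	F10_UM=WT;F10_UF=HET;F10_P=HET;F10_AS1=WT
F12	THBS4	5	10000000	A	G	missense	c.2738A>G	p.(Asp913Gly)		0.000420345	0			32	Deleterious	87	0.95833	0.0	0.85	F12_UM=HET;F12_UF=WT;F12_P=HET
F12	PDHA1	X	11000000	G	A	missense	c.812G>A	p.(Arg271His)		0	0			33	Deleterious	87	0.97536	0.99	2.78	F12_UM=WT;F12_UF=WT;F12_P=HET
F14	PTP4A3	8	12000000	G	A	missense	c.241G>A	p.(Val81Met)		0	0			25.6	Deleterious	87	0.96047	0.13	1.62	F14_UM=HET;F14_UF=HET;F14_P=HOM;F14_US1=HET;F14_US2=HOM
F14	TMEM183A	1	13000000	G	C	missense	c.231G>C	p.(Gln77His)		0.007566204	0			21.6	Deleterious	87	0.93121	0.95	2.54	F14_UM=HET;F14_UF=HET;F14_P=HOM;F14_US1=WT;F14_US2=HOM
F15	PPFIBP1	12	14000000	G	A	splice_site	c.1633+5G>A			0.001261034	0	0	0	14.39	Deleterious	91	0.90405	0.0	-0.17	F15_UM=WT;F15_UF=HET;F15_P=HET;F15_US1=HET;F15_US2=WT;F15_US3=WT
F15	PTCH1	9	15000000	C	T	missense	c.3940C>T	p.(Pro1314Ser)		0.000186116	0.000798722	0.0005	0.0003946	22.6	Deleterious	87	0.99389	1.00	2.86	F15_UM=HET;F15_UF=WT;F15_P=HET;F15_US1=HET;F15_US2=HET;F15_US3=HET
F15	ZFHX3	16	16000000	C	G	missense	c.6685C>G	p.(Pro2229Ala)		0.009667928	0	3.30E-05	2.59E-05	22.9	Neutral	65	0.99653	1.00	-1.68	F15_UM=WT;F15_UF=HET;F15_P=HET;F15_US1=HET;F15_US2=HET;F15_US3=HET
F16	KMT2A	11	17000000	C	T	missense	c.9962C>T	p.(Thr3321Ile)		0.006073598	0.000199681	0.0002	0.0001876	21.9	Neutral	89	0.85724	1.00	6.64	F16_UM=WT;F16_UF=HET;F16_P=HET;F16_US1=WT
F16	NLE1	17	18000000	C	T	missense	c.313C>T	p.(Arg105Cys)		0	0	2.47E-05	6.50E-06	28.2	Deleterious	87	0.95952	0.05	1.07	F16_UM=WT;F16_UF=HET;F16_P=HET;F16_US1=WT
F17	ACSS3	12	19000000	G	A	missense	c.802G>A	p.(Gly268Ser)		0.000420345	0			22.2	Deleterious	87	0.96726	0.0	0.30	F17_UM=HET;F17_UF=WT;F17_P=HET;F17_AS1=WT;F17_US1=HET;F17_US2=HET
F17	SYNE1	6	20000000	G	T	missense	c.5843G>T	p.(Cys1948Phe)		0	0	5.77E-05	5.17E-05	25.6	Deleterious	82	0.99237	0.0	-0.95	F17_UM=WT;F17_UF=HET;F17_P=HET;F17_AS1=WT;F17_US1=HET;F17_US2=HET
F17	NBAS	2	21000000	G	T	missense	c.4692G>T	p.(Gln1564His)		0	0	2.49E-05	6.50E-06	23.1	Neutral	63	0.83271	0.0	-3.06	F17_UM=WT;F17_UF=HET;F17_P=HET;F17_AS1=WT;F17_US1=HET;F17_US2=HET
F19	DNAH1	3	22000000	A	C	missense	c.8854A>C	p.(Ile2952Leu)		0	0			22.1	Neutral	63	0.93847	0.0	-0.89	F19_UM=WT;F19_AF=HET;F19_P=HET;F19_US1=HET;F19_US2=WT
F19	PLCB2	15	23000000	C	T	missense	c.1273C>T	p.(Arg425Trp)	rs369261333	0	0	3.32E-05	3.23E-05	17.48	Deleterious	82	0.88593	0.0	1.53	F19_UM=HET;F19_AF=WT;F19_P=HET;F19_US1=WT;F19_US2=WT
F19	SRRM2	16	24000000	C	G	missense	c.6970C>G	p.(Pro2324Ala)		0	0	0.0001	0.0001035	22.7	Neutral	89	0.89484			F19_UM=HET;F19_AF=HET;F19_P=HET;F19_US1=HET;F19_US2=HET
F19	TLK2	17	25000000	C	T	stop_gain	c.2089C>T	p.(Arg697Ter)		0	0			39	Deleterious	77	0.92219	1.00	5.67	F19_UM=WT;F19_AF=WT;F19_P=HET;F19_US1=WT;F19_US2=WT
F19	SLC9A9	3	26000000	G	A	missense	c.1486G>A	p.(Asp496Asn)	rs111291437	0.00035727	0.000599042	0.001	0.0009185	23.7	Deleterious	82	0.87253	0.0	-0.25	F19_UM=HET;F19_AF=WT;F19_P=HET;F19_US1=HET;F19_US2=HET
F21	GNB4	3	27000000	C	T	missense	c.668C>T	p.(Tyr223Met)	rs144385061	0	0.000399361	0.0002	0.0001423	24.5	Deleterious	87	0.96820	0.63	1.90	F21_UM=HET;F21_UF=HET;F21_P=HOM
F21	SPAG5	17	28000000	C	T	stop_gain	c.3049C>T	p.(Gln1017Ter)		0	0			36	Deleterious	57	0.81069	0.0	0.08	F21_UM=WT;F21_UF=HET;F21_P=HET
F21	DOPEY2	21	29000000	G	C	splice_site	c.2775+5G>C			0.002522068	0			15.00	Deleterious	97	0.99276	0.0	0.22	F21_UM=HET;F21_UF=HET;F21_P=HOM
F22	HEATR1	1	30000000	C	T	missense	c.3803C>T	p.(Pro1268Leu)		0.000840689	0			24.0	Deleterious	87	0.94516	1.00	-1.13	F22_UM=WT;F22_UF=HET;F22_P=HET;F22_AS1=WT;F22_AS2=WT;F22_AS3=HET
F25	PSRC1	1	31000000	C	T	stop_gain	c.919C>T	p.(Arg307Ter)		0.000840689	0	8.60E-06	1.29E-05	36	Neutral	91	0.08066	0.0	0.09	F25_UM=HET;F25_UF=WT;F25_P=HET;F25_AS1=HET;F25_AS2=HET;F25_AS3=HET;F25_US1=HET;F25_US2=WT
F25	KIF21A	12	32000000	C	G	missense	c.4324C>G	p.(Leu1442Val)		0.000250627	0	8.24E-06	6.50E-06	25.9	Deleterious	87	0.99321	0.0	1.12	F25_UM=HET;F25_UF=WT;F25_P=HET;F25_AS1=WT;F25_AS2=HET;F25_AS3=HET;F25_US1=HET;F25_US2=WT
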