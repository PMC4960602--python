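gene	genomic_position	transcript_id	exon	cdna_change	protein_change	exac_maf	sift	polyphen2	mutation_taster	grantham	phylop	gerp	cadd	logit	rank	family
WDR35	2:20137643	NM_001006657	20	C2161T	R721C	4.1E-05	0.00	0.92	1.00	180	9.81	5.04	27.70	0.13	1	CL1
PTHLH	12:28122357	NM_002820	3	G71A	G24E	-	0.00	1.00	0.99	98	5.75	5.13	32.00	0.39	2	CL2
GPC6	13:94482686	NM_005708	3	T599A	F200Y	-	0.00	0.98	0.95	22	7.65	5.48	31.00	0.06	3	CL1
INPPL1	11:71939494	NM_001567	3	G349A	V117I	-	0.00	0.95	0.04	29	8.18	3.90	22.80	0.11	4	CL1
MYH3	17:10539158	NM_002470	29	G3869A	R1290H	3.3E-05	0.00	0.10	0.94	29	4.95	4.84	21.30	0.13	5	CL4
AHDC1	1:27876631	NM_001029882	6	C1996G	R666G	8.6E-06	0.00	1.00	0.06	125	8.73	5.08	22.80	0.04	6	CL2
ABCA12	2:215928852	NM_173076	3	C254T	T85I	-	0.99	0.73	0.00	89	4.18	5.30	15.26	0.10	7	CL3
DEAF1	11:654023	NM_021008	11	C1532G	A511G	-	0.00	0.59	1.00	60	9.01	3.03	17.71	0.08	8	CL3
WNT7A	3:13860472	NM_004625	4	G1019A	S340N	-	0.00	0.94	0.99	46	6.07	4.11	23.60	0.06	9	CL1
MSX1	4:4864736	NM_002448	2	C778A	P260T	1.3E-04	0.00	0.61	0.99	38	5.96	4.76	27.60	0.04	10	CL4
CLPTM1	19:45491357	NM_001294	9	A1058G	N353S	8.2E-06	0.04	0.60	0.99	46	6.60	3.01	17.19	0.09	11	CL1
IGF1R	15:99500597	NM_000875	21	C4030G	Q1344E	-	0.00	0.01	0.99	29	4.78	5.24	13.05	0.04	12	CL1
CFDP1	16:75429103	NM_006324	5	A535T	T179S	-	0.00	0.02	0.99	58	2.66	5.54	15.68	0.04	13	CL1
NBAS	2:15651437	NM_015909	10	G784A	G262S	-	0.01	0.09	0.86	56	4.26	4.15	13.81	0.07	14	CL1
COL17A1	10:105795306	NM_000494	49	T3434C	I1145T	1.9E-05	0.00	0.15	0.31	89	5.46	4.39	12.18	0.06	15	CL5
CDON	11:125887051	NM_001243597	6	A860G	N287S	-	0.00	0.34	0.64	46	3.10	5.01	15.32	0.04	16	CL7
SNAP29	22:21224814	NM_004782	2	A427G	N143D	-	0.02	0.34	0.17	23	8.77	3.70	11.41	0.04	17	CL2
NOTCH2	1:120509101	NM_001200001	9	G1465T	V489L	-	0.00	0.08	0.34	32	0.87	5.38	12.51	0.05	18	CL4
MASP1	3:186937872	NM_001879	16	G2087A	G696E	1.7E-05	0.05	0.09	0.37	98	1.65	3.75	14.53	0.06	19	CL6
FREM2	13:39263993	NM_207361	1	A2512G	T838A	8.2E-06	0.00	0.00	1.00	58	2.49	4.44	7.38	0.07	20	CL4
SPRY4	5:141693887	NM_030964	3	C856T	R286C	2.5E-05	0.00	0.88	0.97	180	2.44	4.70	13.49	0.04	21	CL3
ZBTB24	6:109802863	NM_001164313	2	A367G	K123E	-	0.00	0.05	0.32	56	1.52	4.16	14.67	0.03	22	CL4
EVC2	4:5617202	NM_001166136	16	G2536A	E846K	1.6E-05	0.10	0.67	0.27	56	1.14	2.85	16.13	0.03	23	CL2
SCN2A	2:166187894	NM_001040143	13	T2204C	M735T	-	0.04	0.00	0.06	81	0.47	2.35	2.95	0.04	24	CL3
RYR1	19:38976754	NM_000540	34	G5459T	R1820L	-	0.04	0.01	0.71	102	0.93	1.71	8.87	0.03	25	CL5
WT1	11:32456755	NM_024426	1	C137T	A46V	-	0.02	0.00	0.00	64	0.33	0.81	12.21	0.02	26	CL4
INPPL1	11:71949096	NM_001567	27	T3563G	L1188R	1.0E-05	0.10	.	0.01	102	0.44	1.47	10.20	0.01	27	CL1
COL6A2	21:47551876	NM_001849	28	G2470A	V824M	2.9E-04	0.00	.	1.00	21	.	3.62	.	.	-	CL5
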