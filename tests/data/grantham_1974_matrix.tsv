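# Grantham (1974) amino-acid difference matrix, transcribed by hand from the
# published table (lower triangle; residue order as printed). Used only as an
# independent oracle for the formula-based implementation.
	S	R	L	P	T	A	V	G	I	F	Y	C	H	Q	N	K	D	E	M	W
S	0
R	110	0
L	145	102	0
P	74	103	98	0
T	58	71	92	38	0
A	99	112	96	27	58	0
V	124	96	32	68	69	64	0
G	56	125	138	42	59	60	109	0
I	142	97	5	95	89	94	29	135	0
F	155	97	22	114	103	113	50	153	21	0
Y	144	77	36	110	92	112	55	147	33	22	0
C	112	180	198	169	149	195	192	159	198	205	194	0
H	89	29	99	77	47	86	84	98	94	100	83	174	0
Q	68	43	113	76	42	91	96	87	109	116	99	154	24	0
N	46	86	153	91	65	111	133	80	149	158	143	139	68	46	0
K	121	26	107	103	78	106	97	127	102	102	85	202	32	53	94	0
D	65	96	172	108	85	126	152	94	168	177	160	154	81	61	23	101	0
E	80	54	138	93	65	107	121	98	134	140	122	170	40	29	42	56	45	0
M	135	91	15	87	81	84	21	127	10	28	36	196	87	101	142	95	160	126	0
W	177	101	61	147	128	148	88	184	61	40	37	215	115	130	174	110	181	152	67	0
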