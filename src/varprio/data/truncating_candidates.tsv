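gene	genomic_position	transcript_id	exon	cdna_change	protein_change	effect_class	exac_maf	delta_maxent	family
DLG1	3:196846393	NM_001204388	8	923_925del	308_309del	nonframeshift_deletion	-	.	CL4
FRAS1	4:79391228	NM_025074	51	G7354T	E2452X	stopgain	-	.	CL6
WDR11	10:122660583	NM_018117	21	2660_2662del	887_888del	nonframeshift_deletion	-	.	CL3
IGF1R	15:99500507	NM_000875	21	3940_3941insCGTCCTCCC	L1314delinsPSSL	nonframeshift_insertion	-	.	CL1
FBLN1	22:45927140	NM_001996	5	485-5C>-		splicing	-	22	CL1
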