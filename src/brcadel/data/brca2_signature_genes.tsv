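probeset_id	gene	band	t	p_adjusted
222127_s_at	EXOC1	4q12	-7.05	0.0011
223564_s_at	GNB1L	22q11	6.85	0.0011
632_at	GSK3A	19q13	6.42	0.0025
1555377_at	OR4D2	17q22	6.13	0.0030
208429_x_at	HNF4A	20q13	6.12	0.0030
207973_x_at	ACRV1	11q23	6.21	0.0030
218431_at	C14orf133	14q24	-6.01	0.0034
1552510_at	SLC34A3	9q34	5.9	0.0041
204690_at	STX8	17p12	-5.84	0.0044
227630_at	PPP2R5E	14q23	-5.7	0.0047
205621_at	ALKBH1	14q24	-5.69	0.0047
202569_s_at	MARK3	14q32	-5.74	0.0047
216520_s_at	TPT1	13q14	-5.71	0.0047
230055_at	KHDC1	6q13	5.6	0.0048
221966_at	GPR137	11cen	5.62	0.0048
207733_x_at	PSG9	19q13	5.59	0.0048
1555614_at	SUGT1P1	9p13	5.57	0.0048
1552772_at	CLEC4D	12p13	5.57	0.0048
203598_s_at	WBP4	13q14	-5.51	0.0048
1563639_a_at	FHAD1	1p36	5.54	0.0048
234680_at	KRTAP17-1	17q12	5.52	0.0048
1562657_a_at	C10orf90	10q26	5.45	0.0055
236979_at	BCL2L15	1p13	5.39	0.0061
221095_s_at	KCNE2	21q22	5.4	0.0061
213239_at	PIBF1	13q22	-5.36	0.0063
1567257_at	OR1J2	9q34	5.34	0.0064
225389_at	BTBD6	14q32	-5.31	0.0066
207778_at	REG1P	2p12	5.3	0.0066
226005_at	UBE2G1	17p13	-5.25	0.0070
215424_s_at	SNW1	14q24	-5.23	0.0070
1564112_at	FAM71A	1q32	5.25	0.0070
237980_at	LINC00347	13q21	5.24	0.0070
213103_at	STARD13	13q12	-5.18	0.0071
237257_at	RAB4B	19q13	5.19	0.0071
201767_s_at	ELAC2	17p11	-5.2	0.0071
209944_at	ZNF410	14q24	-5.16	0.0071
1558641_at	SPATA24	5q31	5.2	0.0071
212735_at	KIAA0226	3q29	5.17	0.0071
215449_at	TSPO2	6p21	5.15	0.0071
1553253_at	ASB16	17q21	5.14	0.0071
231625_at	SLC22A9	11q13	5.2	0.0071
225312_at	COMMD6	13q22	-5.12	0.0074
217187_at	MUC5AC	11p15	5.1	0.0077
1553728_at	LRRC43	12q24	5.07	0.0079
1552863_a_at	CACNG6	19q13	5.07	0.0079
217095_x_at	NCR1	19q13	5.06	0.0079
223610_at	SEMA5B	3q21	5.06	0.0079
203065_s_at	CAV1	7q31	-5.03	0.0080
202226_s_at	CRK	17p13	-5.04	0.0080
235416_at	LOC643201	5q35	5.03	0.0080
1557827_at	C10orf103	10q22	5.03	0.0080
225187_at	KIAA1967	8p22	-4.98	0.0082
212936_at	FAM172A	5q15	-4.99	0.0082
215898_at	TTLL5	14q24	-4.98	0.0082
212778_at	PACS2	14q32	-5	0.0082
1562914_a_at	FLJ25328	19p13	5	0.0082
215826_x_at	ZNF835	19q13	4.97	0.0084
238158_at	MEIG1	10p13	4.97	0.0084
219499_at	SEC61A2	10p14	4.94	0.0087
207650_x_at	PTGER1	19p13	4.94	0.0087
237188_x_at	SUN5	20q11	4.92	0.0091
1557679_at	C8orf68	8p23	4.91	0.0092
224256_at	LOC100129449	2q23	4.89	0.0095
1564362_x_at	ZNF843	16p11	4.88	0.0097
205970_at	MT3	16q13	4.87	0.0098
1569095_at	LOC731424	4q35	4.87	0.0098
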