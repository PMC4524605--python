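symbol	origin	length_bp	accessions	previously_mapped	GHO	LAG	VSA	LRE	EQU	ACA	GGA
XAB1	LRE	489	AB490344	0	1p	3	2p	1p22.4	1p	–	3
FBXW11	GHO	926	AB792691	0	1p	3	2p	–	1p	1	13
ESR1	LRE	951	AB490345	0	1p	3	2p	1p21.2	1p	–	3
SOX9	LRE	603;717	AB490350;AB490351	0	1q	2	1q	2q11.2–q11.4	2q	–	18
TOB1	LAG	950	AB794087	0	1q	2	1q	–	–	2	18
RUFY1	LRE	545	AB490352	0	1q	2	1q	2q12.2–q21.1	2q	2	13
BRD2	GHO	732	AB792685	0	1q	2	1q	2q22.2	–	–	16
TKT	LRE	943	AB490349	0	1q	2	1q	2q11.1	2q	2	12
ALAS1	LAG	1060	AB794074	0	1q	2	1q	–	–	2	12
ACVR1	LAG	845	AB794073	0	2p	1	2p	–	–	–	7
CACNB4	GHO	1008;1201	AB792686;AB792687	0	2p	1	2q	1q12.2–q13.1	1q	–	7
WT1	LRE	542	AB490347	0	2p	1	2q	1q21.1–q22.1	1q	1	5
DYNC1H1	LRE	997	AB490348	0	2q	1	2q	1q32.1–q32.3	1q	–	5
CYP2C21-like	LAG	1331	AB794068	0	2q	1	2q	–	–	–	–
EEF2	GHO	1037	AB792689	0	3	19	Micro	Micro	1q	1	28
ZNF326	LRE	892	AB490366	0	3	7	8p	4q12.1–q12.3	3q	4	8
RPE65	LAG	1130	AB793733	0	3	7	8p	–	–	–	8
USP49	LAG	1210	AB794088	0	3	7	8q	–	–	4	26
CNTN2	LAG	922	AB793728	0	3	7	8q	–	–	4	26
RBM12	LRE	943	AB490367	0	3	7	8q	4q21.2–q22.1	3q	4	20
RPN2	LAG	1229	AB794084	0	3	7	8q	–	–	–	20
ACO1/IREBP	GHO	1122	AB326219;AB326220	1	4 (ZW)	11–18	1p	2p11.2–p11.4	2p	–	Zq
RPS6	GHO	593	AB326221	1	4 (ZW)	11–18	1p	2p11.3–p12	2p	2	Zp
DMRT1	GHO	637	AB326222	1	4 (ZW)	11–18	1p	2p12–p21	2p	2	Zp
CHD1	GHO	1263	AB326217;AB326218	1	4 (ZW)	11–18	1p	2p21	2p	2	Zq
GHR	GHO	852	AB326214	1	4 (ZW)	11–18	1p	2p22–p23.3	2p	2	Zp
ATP5A1	GHO	990	AB326215;AB326216	1	4 (ZW)	11–18	1p	2p23.1–p23.3	2p	1	Zp
TMEM57	LAG	800	AB794086	0	5	6	Micro	–	–	–	23
RNF19B	LAG	942	AB793732	0	5	6	Micro	–	–	–	23
CUL4B	LRE	723	AB490387	0	5	11–18	Micro	Micro	–	–	4p
ATRX	LRE	804	AB490386	0	5	11–18	Micro	Micro	Micro	–	4p
AR	LRE	941	AB490385	0	5	11–18	Micro	Micro	Micro	–	4p
CHD2	LRE	654;692	AB490388;AB490389	0	6q	11–18	Micro	Micro	–	–	10
HDAC3	GHO	976	AB792692	0	6q	8	7p	4p11.1–p11.2	3p	4	13
SS18	GHO	881	AB792697	0	6q	8	7q	4p12.2–p21.2	3p	4	2q
ENPP2	LRE	961	AB490363	0	6q	8	7q	4p22.2–p22.4	3p	–	2q
POLG	LAG	1565	AB794083	0	6q	11–18	Micro	–	Micro	–	10
UCHL1	LRE	595	AB490372	0	7	10	3p	5p11.1–p12.1	6p	5	4q
EXOC1	GHO	1171	AB792690	0	7	10	3q	5p11.2–p12.2	7p	5	4q
ACSL1	LRE	748	AB490370	0	7	10	3q	5p12.1–p12.2	7q	5	4q
DCLK2	LRE	688	AB490369	0	7	10	3q	5p12.1–p21	–	5	4q
SMAD1	LAG	944	AB794085	0	7	10	3q	–	–	5	4q
RAP1GDS1	GHO	1044	AB792702	0	7	10	3q	5p21–p22.2	7q	–	4q
CTNNB1	LRE	1201	AB490379	0	8	11–18	4q	6q11	Zp	6	2p
TOP2B	LAG	1639	AB793737	0	8	11–18	4q	–	–	–	2p
WAC	GHO	858	AB792701	0	8	11–18	4q	6q21–q23	Zp	6	2p
GAD2	LRE	672	AB490380	0	8	11–18	4q	6q21–q23	Zp	6	2p
ARNT	LAG	1034	AB794075	0	9	11–18	Micro	–	–	–	25
ENO1	LAG	917	AB794078	0	9	6	Micro	–	Micro	–	21
DNM1	LAG	1014	AB794076	0	9	6	Micro	–	Micro	–	17
PPP2R1A	LAG	1169	AB793731	0	9	6	Micro	–	–	–	–
GRIN1	LAG	893	AB794080	0	9	6	Micro	–	Micro	–	17
EEF2K	LAG	970	AB794077	0	10	11–18	Micro	–	Micro	–	14
UBN1	LAG	1153	AB794072	0	10	11–18	Micro	–	–	–	14
PDXDC1	LAG	1619	AB794082	0	10	11–18	Micro	–	–	–	14
HSPA8	GHO	952	AB792693	0	10	11–18	Micro	Micro	Micro	Micro	24
NF2	LRE	940	AB490393	0	11	11–18	Micro	Micro	–	–	15
SF3A1	LRE	937	AB490394	0	11	11–18	Micro	Micro	–	–	15
ATP2A2	GHO	1023	AB792684	0	11	11–18	Micro	Micro	Micro	Micro	15
SBNO1	GHO	1050	AB792695	0	11	11–18	Micro	Micro	–	Micro	15
MYST2	GHO	1315	AB792694	0	12	11–18	4p	6p21.1–p22.2	Zq	6	27
STAT3	LAG	1654	AB793734	0	12	11–18	4p	–	–	6	27
TOP2A	LAG	882;477	AB793735;AB793736	0	12	11–18	4p	–	–	6	27
TPT1	LRE	438	AB490359	0	13q	4	5q	3p11.1–q11	4p	–	1q
IPO5	LAG	703;492	AB793729;AB793730	0	13q	4	5q	–	–	3	1q
EIF2S3	LRE	733	AB490361	0	13q	4	5q	3q12.3–q21.1	4p	3	1q
OCA2	LRE	782	AB490360	0	13q	4	5q	3q12.1–q12.2	–	3	1q
BRD7	LRE	784	AB490390	0	13q	11–18	Micro	Micro	Micro	–	11
ELMOD1	LRE	682	AB490362	0	13q	4	5q	3q22.1–q22.3	4q	–	1q
ACTN4	LRE	1069	AB490396	0	14p	11–18	Micro	Micro	–	–	–
DYRK2	GHO	1011	AB792688	0	14q	9	3p	5q12–q21.2	–	–	1p
RANGAP1	LRE	1024	AB490374	0	14q	9	3p	5q21.2–q22.1	6q	5	1p
TTC26	GHO	744	AB792700	0	14q	9	3p	5q21.3–q22.3	6q	–	1p
SOX5	LRE	851;705	AB490376;AB490377	0	14q	9	3p	5q22.1–q22.4	–	5	1p
ADAM12	LAG	933	AB794067	0	15q	5 (Z)	6q	–	–	3	6
PSAP	LRE	1325	AB490358	0	15q	5 (Z)	6q	3p11.2–p12.2	5q	–	6
BTRC	LRE	889	AB490357	0	15q	5 (Z)	6q	3p21.1–p21.2	–	–	6
SH3PXD2A	GHO	1235	AB792696	0	15q	5 (Z)	6q	3p22.1	5q	3	6
SLIT1	LAG	995	AB794071	0	15q	5 (Z)	6q	–	–	–	6
SKIL	LAG	1686	AB794070	0	15q	5 (Z)	6q	–	–	3	9
EPHA4	LAG	888	AB794079	0	15q	5 (Z)	6q	–	–	3	9
TLOC1	GHO	836	AB792698	0	15q	5 (Z)	6q	3p22.3	5q	3	9
NCL	LAG	1780	AB794069	0	15q	5 (Z)	6q	–	–	–	9
KRT8	LAG	835	AB794081	0	16q	2	Micro	–	–	–	–
TRIM37	GHO	1186	AB792699	0	17q	1	Micro	Micro	1p	–	19
AMH	EQU	712;709	AB794387;AB794388	0	17q	1	Micro	–	–	–	19
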