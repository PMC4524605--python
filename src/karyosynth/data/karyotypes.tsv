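species	diploid_number	fundamental_number	sex_system	chromosome	morphology	size_class	copies	sex
GHO	38	42	ZW	1	submetacentric	macro	2
GHO	38	42	ZW	2	submetacentric	macro	2
GHO	38	42	ZW	3	acrocentric	macro	2
GHO	38	42	ZW	4	acrocentric	macro	1	Z
GHO	38	42	ZW	W	subtelocentric	macro	1	W
GHO	38	42	ZW	5	acrocentric	macro	2
GHO	38	42	ZW	6	subtelocentric	macro	2
GHO	38	42	ZW	7	acrocentric	macro	2
GHO	38	42	ZW	8	acrocentric	macro	2
GHO	38	42	ZW	9	acrocentric	macro	2
GHO	38	42	ZW	10	acrocentric	macro	2
GHO	38	42	ZW	11	acrocentric	macro	2
GHO	38	42	ZW	12	acrocentric	macro	2
GHO	38	42	ZW	13	subtelocentric	macro	2
GHO	38	42	ZW	14	subtelocentric	macro	2
GHO	38	42	ZW	15	subtelocentric	macro	2
GHO	38	42	ZW	16	submetacentric	macro	2
GHO	38	42	ZW	17	subtelocentric	macro	2
GHO	38	42	ZW	18	metacentric	macro	2
GHO	38	42	ZW	19	submetacentric	macro	2
LAG	38		ZW	1	acrocentric	macro	2
LAG	38		ZW	2	acrocentric	macro	2
LAG	38		ZW	3	acrocentric	macro	2
LAG	38		ZW	4	acrocentric	macro	2
LAG	38		ZW	5	acrocentric	macro	1	Z
LAG	38		ZW	W	acrocentric	macro	1	W
LAG	38		ZW	6	acrocentric	macro	2
LAG	38		ZW	7	acrocentric	macro	2
LAG	38		ZW	8	acrocentric	macro	2
LAG	38		ZW	9	acrocentric	macro	2
LAG	38		ZW	10	acrocentric	macro	2
LAG	38		ZW	11	micro	micro	2
LAG	38		ZW	12	micro	micro	2
LAG	38		ZW	13	micro	micro	2
LAG	38		ZW	14	micro	micro	2
LAG	38		ZW	15	micro	micro	2
LAG	38		ZW	16	micro	micro	2
LAG	38		ZW	17	micro	micro	2
LAG	38		ZW	18	micro	micro	2
LAG	38		ZW	19	acrocentric	macro	2
VSA	40		ZW	1	metacentric	macro	2
VSA	40		ZW	2	metacentric	macro	2
VSA	40		ZW	3	submetacentric	macro	2
VSA	40		ZW	4	submetacentric	macro	2
VSA	40		ZW	5	submetacentric	macro	2
VSA	40		ZW	6	submetacentric	macro	2
VSA	40		ZW	7	submetacentric	macro	2
VSA	40		ZW	8	submetacentric	macro	2
VSA	40		ZW	micro-01	micro	micro	2
VSA	40		ZW	micro-02	micro	micro	2
VSA	40		ZW	micro-03	micro	micro	2
VSA	40		ZW	micro-04	micro	micro	2
VSA	40		ZW	micro-05	micro	micro	2
VSA	40		ZW	micro-06	micro	micro	2
VSA	40		ZW	micro-07	micro	micro	2
VSA	40		ZW	micro-08	micro	micro	2
VSA	40		ZW	micro-09	micro	micro	2
VSA	40		ZW	micro-10	micro	micro	2
VSA	40		ZW	micro-11	micro	micro	2
VSA	40		ZW	micro-12	micro	micro	2
LRE	36		unknown	1	metacentric	macro	2
LRE	36		unknown	2	metacentric	macro	2
LRE	36		unknown	3	submetacentric	macro	2
LRE	36		unknown	4	submetacentric	macro	2
LRE	36		unknown	5	submetacentric	macro	2
LRE	36		unknown	6	submetacentric	macro	2
LRE	36		unknown	micro-01	micro	micro	2
LRE	36		unknown	micro-02	micro	micro	2
LRE	36		unknown	micro-03	micro	micro	2
LRE	36		unknown	micro-04	micro	micro	2
LRE	36		unknown	micro-05	micro	micro	2
LRE	36		unknown	micro-06	micro	micro	2
LRE	36		unknown	micro-07	micro	micro	2
LRE	36		unknown	micro-08	micro	micro	2
LRE	36		unknown	micro-09	micro	micro	2
LRE	36		unknown	micro-10	micro	micro	2
LRE	36		unknown	micro-11	micro	micro	2
LRE	36		unknown	micro-12	micro	micro	2
EQU	36		ZW	1	submetacentric	macro	2
EQU	36		ZW	2	submetacentric	macro	2
EQU	36		ZW	3	submetacentric	macro	2
EQU	36		ZW	4	submetacentric	macro	2
EQU	36		ZW	5	submetacentric	macro	2
EQU	36		ZW	6	submetacentric	macro	2
EQU	36		ZW	7	submetacentric	macro	2
EQU	36		ZW	Z	submetacentric	macro	2	Z
EQU	36		ZW	micro-01	micro	micro	2
EQU	36		ZW	micro-02	micro	micro	2
EQU	36		ZW	micro-03	micro	micro	2
EQU	36		ZW	micro-04	micro	micro	2
EQU	36		ZW	micro-05	micro	micro	2
EQU	36		ZW	micro-06	micro	micro	2
EQU	36		ZW	micro-07	micro	micro	2
EQU	36		ZW	micro-08	micro	micro	2
EQU	36		ZW	micro-09	micro	micro	2
EQU	36		ZW	micro-10	micro	micro	2
ACA	36		unknown	1	metacentric	macro	2
ACA	36		unknown	2	metacentric	macro	2
ACA	36		unknown	3	metacentric	macro	2
ACA	36		unknown	4	metacentric	macro	2
ACA	36		unknown	5	metacentric	macro	2
ACA	36		unknown	6	metacentric	macro	2
ACA	36		unknown	micro-01	micro	micro	2
ACA	36		unknown	micro-02	micro	micro	2
ACA	36		unknown	micro-03	micro	micro	2
ACA	36		unknown	micro-04	micro	micro	2
ACA	36		unknown	micro-05	micro	micro	2
ACA	36		unknown	micro-06	micro	micro	2
ACA	36		unknown	micro-07	micro	micro	2
ACA	36		unknown	micro-08	micro	micro	2
ACA	36		unknown	micro-09	micro	micro	2
ACA	36		unknown	micro-10	micro	micro	2
ACA	36		unknown	micro-11	micro	micro	2
ACA	36		unknown	micro-12	micro	micro	2
GGA	78		ZW	1	metacentric	macro	2
GGA	78		ZW	2	submetacentric	macro	2
GGA	78		ZW	3	acrocentric	macro	2
GGA	78		ZW	4	submetacentric	macro	2
GGA	78		ZW	5	acrocentric	macro	2
GGA	78		ZW	6	acrocentric	macro	2
GGA	78		ZW	7	acrocentric	macro	2
GGA	78		ZW	8	acrocentric	macro	2
GGA	78		ZW	Z	metacentric	macro	1	Z
GGA	78		ZW	W	submetacentric	macro	1	W
GGA	78		ZW	9	micro	micro	2
GGA	78		ZW	10	micro	micro	2
GGA	78		ZW	11	micro	micro	2
GGA	78		ZW	12	micro	micro	2
GGA	78		ZW	13	micro	micro	2
GGA	78		ZW	14	micro	micro	2
GGA	78		ZW	15	micro	micro	2
GGA	78		ZW	16	micro	micro	2
GGA	78		ZW	17	micro	micro	2
GGA	78		ZW	18	micro	micro	2
GGA	78		ZW	19	micro	micro	2
GGA	78		ZW	20	micro	micro	2
GGA	78		ZW	21	micro	micro	2
GGA	78		ZW	22	micro	micro	2
GGA	78		ZW	23	micro	micro	2
GGA	78		ZW	24	micro	micro	2
GGA	78		ZW	25	micro	micro	2
GGA	78		ZW	26	micro	micro	2
GGA	78		ZW	27	micro	micro	2
GGA	78		ZW	28	micro	micro	2
GGA	78		ZW	29	micro	micro	2
GGA	78		ZW	30	micro	micro	2
GGA	78		ZW	31	micro	micro	2
GGA	78		ZW	32	micro	micro	2
GGA	78		ZW	33	micro	micro	2
GGA	78		ZW	34	micro	micro	2
GGA	78		ZW	35	micro	micro	2
GGA	78		ZW	36	micro	micro	2
GGA	78		ZW	37	micro	micro	2
GGA	78		ZW	38	micro	micro	2
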