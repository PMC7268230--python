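region_index	short_name
1	BSTS
2	CAC
3	CMF
4	CC
5	Cu
6	En
7	Fu
8	IP
9	IT
10	IC
11	LO
12	LOF
13	Li
14	MOF
15	MT
16	PH
17	PaC
18	Op
19	Or
20	Tr
21	PeC
22	PoC
23	PoCi
24	PrC
25	PrCu
26	RAC
27	RMF
28	SF
29	SP
30	ST
31	SM
32	FP
33	TP
34	TT
35	Ins
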