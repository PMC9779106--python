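rank	code	acronym	coverage	cse
1	A14	MIIT	43.66	237.84
2	A1	NHC	42.58	230.48
3	A11	NATCM	12.73	46.73
4	A2	MCA	10.97	37.89
5	A12	CNCA	10.93	37.71
6	A17	CBIRC	10.88	37.49
7	A3	NDRC	4.95	11.44
8	A4	MOE	4.85	11.06
9	A19	MEM	4.64	10.26
10	A7	MNR	3.57	6.55
11	A5	MOF	3.22	5.42
12	A10	NHSA	2.94	4.56
13	A13	MARA	2.13	2.33
14	A9	SAMR	2.11	2.26
15	A8	MOHURD	1.76	1.44
16	A6	MHRSS	1.70	1.31
17	A16	STA	1.57	1.01
18	B2	ACWF	1.45	0.77
19	A15	PBC	1.00	0
20	A18	CSRC	1.00	0
21	B1	CCCYL	1.00	0
22	B3	RCS	1.00	0
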