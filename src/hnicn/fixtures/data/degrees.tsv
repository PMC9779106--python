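code	acronym	out_degree	in_degree
A1	NHC	21	14
A2	MCA	15	16
A3	NDRC	7	11
A4	MOE	3	11
A5	MOF	2	9
A6	MHRSS	2	7
A7	MNR	6	5
A8	MOHURD	5	6
A9	SAMR	7	5
A10	NHSA	9	7
A11	NATCM	4	5
A12	CNCA	7	7
A13	MARA	7	5
A14	MIIT	20	5
A15	PBC	0	5
A16	STA	10	4
A17	CBIRC	10	6
A18	CSRC	0	2
A19	MEM	1	3
B1	CCCYL	1	3
B2	ACWF	4	3
B3	RCS	0	2
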