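code	acronym	dis_plus	dis_minus	closeness	weight_node
A1	NHC	0.159	0.384	0.707	0.188
A2	MCA	0.254	0.344	0.575	0.153
A5	MOF	0.371	0.200	0.350	0.093
A7	MNR	0.404	0.165	0.290	0.077
A4	MOE	0.355	0.144	0.288	0.077
A10	NHSA	0.396	0.152	0.277	0.074
A6	MHRSS	0.380	0.097	0.204	0.054
A3	NDRC	0.391	0.090	0.187	0.050
A14	MIIT	0.406	0.082	0.169	0.045
A11	NATCM	0.416	0.080	0.161	0.043
A15	PBC	0.431	0.082	0.161	0.043
A9	SAMR	0.428	0.038	0.081	0.022
A16	STA	0.444	0.025	0.054	0.014
A13	MARA	0.446	0.023	0.049	0.013
A8	MOHURD	0.444	0.022	0.046	0.012
A12	CNCA	0.446	0.020	0.044	0.012
A19	MEM	0.448	0.019	0.040	0.011
B2	ACWF	0.451	0.011	0.023	0.006
A17	CBIRC	0.452	0.010	0.022	0.006
B1	CCCYL	0.451	0.010	0.021	0.006
A18	CSRC	0.456	0.006	0.013	0.004
B3	RCS	0.458	0.001	0.003	0.001
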