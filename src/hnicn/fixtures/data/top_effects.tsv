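rank	pair	effect_pct
1	A1-A14	84.572
2	A11-A14	20.275
3	A1-A11	19.648
4	A2-A14	16.440
5	A12-A14	16.361
6	A14-A17	16.268
7	A1-A2	15.931
8	A1-A12	15.855
9	A1-A17	15.763
10	A3-A14	4.964
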