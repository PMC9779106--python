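aspect	inf_entropy	inf_utility	weight_index
main-policies	0.9921	0.0079	0.2430
medical-resources	0.9951	0.0049	0.1508
natural-resources	0.9949	0.0051	0.1571
economic-support	0.9939	0.0061	0.1892
personnel-training	0.9916	0.0084	0.2599
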