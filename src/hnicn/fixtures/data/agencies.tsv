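code	canonical_name	aliases	prefix	middle	tagged	category
A1	The National Health Commission of the People's Republic of China	NHC	The National	Health	Commission	government-department
A2	The Ministry of Civil Affairs of the People's Republic of China	MCA	The	Civil Affairs	Ministry	government-department
A3	The National Development and Reform Commission	NDRC	The National	Development and Reform	Commission	government-department
A4	The Ministry of Education of the People's Republic of China	MOE	The	Education	Ministry	government-department
A5	The Ministry of Finance of the People's Republic of China	MOF	The	Finance	Ministry	government-department
A6	The Ministry of Human Resources and Social Security of the People's Republic of China	MHRSS	The	Human Resources and Social Security	Ministry	government-department
A7	The Ministry of Natural Resources of the People's Republic of China	MNR	The	Natural Resources	Ministry	government-department
A8	The Ministry of Housing and Urban-Rural Development of the People's Republic of China	MOHURD	The	Housing and Urban-Rural Development	Ministry	government-department
A9	The State Administration for Market Regulation	SAMR	The State	Market Regulation	Administration	government-department
A10	The National Healthcare Security Administration	NHSA	The National	Healthcare Security	Administration	government-department
A11	The National Administration of Traditional Chinese Medicine	NATCM	The National	Traditional Chinese Medicine	Administration	government-department
A12	The China National Committee on Aging	CNCA	The China National	Aging	Committee	government-department
A13	The Ministry of Agriculture and Rural Affairs of the People's Republic of China	MARA	The	Agriculture and Rural Affairs	Ministry	government-department
A14	The Ministry of Industry and Information Technology of the People's Republic of China	MIIT	The	Industry and Information Technology	Ministry	government-department
A15	The People's Bank of China	PBC	The	People's	Bank	government-department
A16	The State Taxation Administration	STA	The State	Taxation	Administration	government-department
A17	The China Banking and Insurance Regulatory Commission	CBIRC	The China	Banking and Insurance Regulatory	Commission	government-department
A18	The China Securities Regulatory Commission	CSRC	The China	Securities Regulatory	Commission	government-department
A19	The Ministry of Emergency Management of the People's Republic of China	MEM	The	Emergency Management	Ministry	government-department
B1	The Central Committee of the Communist Youth League of China	CCCYL	The Central	Communist Youth League	Committee	public-organization
B2	The All-China Women's Federation	ACWF	The All-China	Women's	Federation	public-organization
B3	The Red Cross Society of China	RCS	The Red Cross	China	Society	public-organization
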