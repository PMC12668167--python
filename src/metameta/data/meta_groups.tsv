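group	trait	trait_id	k_studies	total_n	p_value
Meta1	Cannabis Use	EFO_0007585	7	1190454	6.5E-08
Meta2	Cannabis Dependence	EFO_0007191	5	568944	1.48E-05
Meta3	Cannabis Dependence Measurement	EFO_0008457	1	14754	2E-08
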