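rsid	effect_allele	other_allele	beta	se	pvalue	eaf	n	gene_label	chrom	pos	trait_type
rs4410790	T	C	0.109	0.015	1.80e-10	0.36	9876	AHR			continuous
rs2472297	C	T	0.150	0.016	1.00e-17	0.73	9876	CYP1A2			continuous
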