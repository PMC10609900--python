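rsid	effect_allele	other_allele	beta	se	pvalue	eaf	n	gene_label	chrom	pos	trait_type
rs4410790	C	T	0.150	0.017	2.36e-19	0.38	47000	AHR			continuous
rs2470893	T	C	0.120	0.016	5.15e-14	0.31	47000	CYP1A2			continuous
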