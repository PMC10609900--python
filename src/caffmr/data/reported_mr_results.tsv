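exposure	outcome	scale	estimate	ci_low	ci_high	pvalue	consistent_ci
plasma_caffeine	log_eGFRcrea	beta	-0.025	-0.028	-0.022	4.1e-53	yes
plasma_caffeine	log_eGFRcyst	beta	-0.018	-0.025	-0.011	1.6e-6	yes
plasma_caffeine	log_UACR	beta	-0.179	-0.215	-0.143	1.7e-22	yes
plasma_caffeine	urinary_sodium	beta	0.149	0.115	0.170	1.6e-24	no
plasma_caffeine	BUN	beta	0.04	0.025	0.055	1.9e-7	yes
caffeine_intake	log_eGFRcrea	beta	0.020	0.014	0.015	1.8e-11	no
caffeine_intake	log_eGFRcyst	beta	0.013	0.03	0.02	0.01	no
caffeine_intake	log_UACR	beta	0.163	0.120	0.206	1.6e-3	no
caffeine_intake	CKD	odds_ratio	0.84	0.75	0.94	0.003	yes
caffeine_intake	urinary_sodium	beta	-0.125	-0.158	-0.093	2.6e-14	yes
caffeine_intake	BUN	beta	-0.034	-0.064	-0.005	0.023	yes
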