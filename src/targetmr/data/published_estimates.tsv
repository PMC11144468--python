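label	source	instrument	or	ci_low	ci_high	scale	n_cases
urti	CKB	locus	2.18	1.34	3.53	per-SD-ldl	1095
urti	UKB	locus	1.70	1.15	2.51	per-SD-ldl	2364
asthma	CKB	locus	2.28	1.12	4.64	per-SD-ldl	427
asthma	UKB	locus	1.15	1.02	1.28	per-SD-ldl	39269
urti	CKB	ldl_grs	1.11	0.88	1.38	per-SD-ldl
carotid_plaque	CKB	locus	0.61	0.45	0.83	per-SD-ldl	8340
liver_disease	CKB	locus	2.10	1.17	3.79	per-SD-ldl
copd_hospitalisation	CKB	locus	1.38	1.08	1.76	per-SD-ldl	6836
copd_exacerbation	CKB	locus	1.91	1.12	3.24	per-SD-ldl	2212
copd_exacerbation_fatal	CKB	locus	3.61	1.71	7.60	per-SD-ldl	730
copd_exacerbation_fatal	CKB	ldl_grs	0.92	0.75	1.19	per-SD-ldl
copd_nonfatal	CKB	locus	1.38	1.05	1.80	per-SD-ldl	5204
move	CKB	locus	0.80	0.67	0.95	per-SD-ldl	15752
ischaemic_stroke	CKB	locus	0.80	0.66	0.98	per-SD-ldl	11467
intracerebral_haemorrhage	CKB	locus	1.04	0.81	1.34	per-SD-ldl	5906
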