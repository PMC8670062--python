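trait	code	super_population	phenotype_value	phenotype_kind	sex_stratum
lactase_persistence	ASW	AFR	0.25	prevalence	combined
lactase_persistence	ESN	AFR	0.13	prevalence	combined
lactase_persistence	GWD	AFR	0.430	prevalence	combined
lactase_persistence	LWK	AFR	0.61	prevalence	combined
lactase_persistence	MSL	AFR	0.52	prevalence	combined
lactase_persistence	YRI	AFR	0.13	prevalence	combined
lactase_persistence	CLM	AMR	0.2	prevalence	combined
lactase_persistence	MXL	AMR	0.52	prevalence	combined
lactase_persistence	PEL	AMR	0.06	prevalence	combined
lactase_persistence	CDX	EAS	0.15	prevalence	combined
lactase_persistence	CHB	EAS	0.15	prevalence	combined
lactase_persistence	CHS	EAS	0.15	prevalence	combined
lactase_persistence	JPT	EAS	0.27	prevalence	combined
lactase_persistence	KHV	EAS	0.02	prevalence	combined
lactase_persistence	CEU	EUR	0.87	prevalence	combined
lactase_persistence	FIN	EUR	0.81	prevalence	combined
lactase_persistence	GBR	EUR	0.92	prevalence	combined
lactase_persistence	IBS	EUR	0.71	prevalence	combined
lactase_persistence	TSI	EUR	0.28	prevalence	combined
lactase_persistence	BEB	SAS	0.175	prevalence	combined
lactase_persistence	GIH	SAS	0.39	prevalence	combined
lactase_persistence	ITU	SAS	0.39	prevalence	combined
lactase_persistence	PJL	SAS	0.42	prevalence	combined
lactase_persistence	STU	SAS	0.27	prevalence	combined
melanoma	ACB	AFR	4.2e-5	prevalence	combined
melanoma	ASW	AFR	2.9e-5	prevalence	combined
melanoma	ESN	AFR	5.7e-6	prevalence	combined
melanoma	LWK	AFR	1.4e-5	prevalence	combined
melanoma	MSL	AFR	5.6e-6	prevalence	combined
melanoma	YRI	AFR	5.7e-6	prevalence	combined
melanoma	CLM	AMR	1.08e-4	prevalence	combined
melanoma	MXL	AMR	6.9e-5	prevalence	combined
melanoma	PEL	AMR	8.3e-5	prevalence	combined
melanoma	PUR	AMR	1.11e-4	prevalence	combined
melanoma	CDX	EAS	1.5e-5	prevalence	combined
melanoma	CHB	EAS	1.5e-5	prevalence	combined
melanoma	CHS	EAS	1.5e-5	prevalence	combined
melanoma	JPT	EAS	5.0e-5	prevalence	combined
melanoma	KHV	EAS	4.3e-6	prevalence	combined
melanoma	CEU	EUR	1.3e-3	prevalence	combined
melanoma	FIN	EUR	1.04e-3	prevalence	combined
melanoma	GBR	EUR	9.39e-4	prevalence	combined
melanoma	IBS	EUR	3.92e-4	prevalence	combined
melanoma	TSI	EUR	7.12e-4	prevalence	combined
melanoma	BEB	SAS	6.5e-6	prevalence	combined
melanoma	GIH	SAS	5.4e-6	prevalence	combined
melanoma	ITU	SAS	5.4e-6	prevalence	combined
melanoma	PJL	SAS	4.6e-6	prevalence	combined
melanoma	STU	SAS	1.4e-5	prevalence	combined
multiple_sclerosis	ACB	AFR	1.36e-4	prevalence	combined
multiple_sclerosis	ESN	AFR	3.71e-5	prevalence	combined
multiple_sclerosis	GWD	AFR	3.35e-5	prevalence	combined
multiple_sclerosis	LWK	AFR	3.30e-5	prevalence	combined
multiple_sclerosis	MSL	AFR	2.89e-5	prevalence	combined
multiple_sclerosis	YRI	AFR	3.71e-5	prevalence	combined
multiple_sclerosis	CLM	AMR	5.53e-5	prevalence	combined
multiple_sclerosis	MXL	AMR	1.08e-4	prevalence	combined
multiple_sclerosis	PEL	AMR	6.98e-5	prevalence	combined
multiple_sclerosis	PUR	AMR	1.9e-4	prevalence	combined
multiple_sclerosis	CDX	EAS	7.30e-5	prevalence	combined
multiple_sclerosis	CHB	EAS	7.30e-5	prevalence	combined
multiple_sclerosis	CHS	EAS	7.30e-5	prevalence	combined
multiple_sclerosis	JPT	EAS	3.62e-4	prevalence	combined
multiple_sclerosis	KHV	EAS	4.41e-5	prevalence	combined
multiple_sclerosis	FIN	EUR	1.49e-3	prevalence	combined
multiple_sclerosis	GBR	EUR	1.61e-3	prevalence	combined
multiple_sclerosis	IBS	EUR	9.41e-4	prevalence	combined
multiple_sclerosis	TSI	EUR	1.19e-3	prevalence	combined
multiple_sclerosis	BEB	SAS	1.42e-4	prevalence	combined
multiple_sclerosis	GIH	SAS	1.54e-4	prevalence	combined
multiple_sclerosis	ITU	SAS	1.54e-4	prevalence	combined
multiple_sclerosis	PJL	SAS	1.46e-4	prevalence	combined
multiple_sclerosis	STU	SAS	3.35e-5	prevalence	combined
height_male	ACB	AFR	175.9	quantitative	male
height_male	ASW	AFR	175.5	quantitative	male
height_male	ESN	AFR	165.9	quantitative	male
height_male	GWD	AFR	165.4	quantitative	male
height_male	LWK	AFR	169.6	quantitative	male
height_male	MSL	AFR	164.4	quantitative	male
height_male	YRI	AFR	165.9	quantitative	male
height_male	CLM	AMR	169.5	quantitative	male
height_male	MXL	AMR	169.0	quantitative	male
height_male	PEL	AMR	165.2	quantitative	male
height_male	PUR	AMR	172.1	quantitative	male
height_male	CDX	EAS	171.8	quantitative	male
height_male	CHB	EAS	171.8	quantitative	male
height_male	CHS	EAS	171.8	quantitative	male
height_male	JPT	EAS	170.8	quantitative	male
height_male	KHV	EAS	164.5	quantitative	male
height_male	CEU	EUR	177.4	quantitative	male
height_male	FIN	EUR	179.6	quantitative	male
height_male	GBR	EUR	177.5	quantitative	male
height_male	IBS	EUR	176.6	quantitative	male
height_male	TSI	EUR	177.8	quantitative	male
height_male	BEB	SAS	163.8	quantitative	male
height_male	GIH	SAS	165.0	quantitative	male
height_male	ITU	SAS	165.0	quantitative	male
height_male	PJL	SAS	167.0	quantitative	male
height_male	STU	SAS	165.7	quantitative	male
height_female	ACB	AFR	165.3	quantitative	female
height_female	ASW	AFR	162.6	quantitative	female
height_female	ESN	AFR	156.3	quantitative	female
height_female	GWD	AFR	160.9	quantitative	female
height_female	LWK	AFR	158.2	quantitative	female
height_female	MSL	AFR	156.6	quantitative	female
height_female	YRI	AFR	156.3	quantitative	female
height_female	CLM	AMR	156.95	quantitative	female
height_female	MXL	AMR	156.9	quantitative	female
height_female	PEL	AMR	152.9	quantitative	female
height_female	PUR	AMR	159.2	quantitative	female
height_female	CDX	EAS	159.7	quantitative	female
height_female	CHB	EAS	159.7	quantitative	female
height_female	CHS	EAS	159.7	quantitative	female
height_female	JPT	EAS	158.3	quantitative	female
height_female	KHV	EAS	153.6	quantitative	female
height_female	CEU	EUR	163.3	quantitative	female
height_female	FIN	EUR	165.9	quantitative	female
height_female	GBR	EUR	164.4	quantitative	female
height_female	IBS	EUR	163.4	quantitative	female
height_female	TSI	EUR	164.6	quantitative	female
height_female	BEB	SAS	150.8	quantitative	female
height_female	GIH	SAS	152.6	quantitative	female
height_female	ITU	SAS	152.6	quantitative	female
height_female	PJL	SAS	153.8	quantitative	female
height_female	STU	SAS	154.6	quantitative	female
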