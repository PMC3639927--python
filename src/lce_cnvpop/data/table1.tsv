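region	population	acgh_log2	cnv_pp_pct	cnv_het_pct	cnv_mm_pct	allele_plus_pct	allele_minus_pct	snp_aa_pct	snp_ag_pct	snp_gg_pct
Sub-Saharan Africans	PYG	-0.13	38.6	52.3	9.1	64.77	35.23	0	13.64	86.36
Sub-Saharan Africans	YRI	0	36.4	59.1	4.5	65.91	34.09	0	28.57	71.43
Sub-Saharan Africans	BAN	-0.03	44.4	55.6	0	72.22	27.78	0	50.00	50.00
North-Africans/Middle East	ALG	-0.3	11.5	42.3	46.2	32.69	67.31	0	21.43	78.57
North-Africans/Middle East	BED	-0.21	19.4	55.6	25	47.22	52.78	14.63	53.66	31.71
Europeans	FRA	-0.2	22.2	37	40.7	40.74	59.26	16.67	41.67	41.67
Southern Asians	BRA	-0.31	22.7	40.9	36.4	43.18	56.82	21.74	43.48	34.78
Southern Asians	HAZ	-0.15	58.9	41.1	0	79.41	20.59	43.75	56.25	0
Eastern Asians	CHB	-0.26	14.7	47.1	38.2	38.24	61.76	0	52.17	47.83
Eastern Asians	YAK	-0.12	63.6	27.3	9.1	77.27	22.73	50.00	31.82	18.18
Oceania	OCE	-0.18	31.4	37.1	31.4	50.00	50.00	26.47	41.18	32.35
Americans	PIMA	-0.67	9.1	31.9	59.1	25.00	75.00	9.09	36.36	54.55
Americans	MAYA	-0.27	9.5	57.1	33.3	38.10	61.90	7.14	57.14	35.71
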