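region	population	n	hwe_chi2	hwe_p	allele_plus_pct	allele_minus_pct	snp_aa_pct	snp_ag_pct	snp_gg_pct	ld_r2
Sub-Saharan Africans	PYG	44	0.93	0.33	64.77	35.23	0	13.64	86.36	0.013
Sub-Saharan Africans	MAN	17	0.78	0.56	58.82	41.18	4.55	22.73	72.73	0.121
Sub-Saharan Africans	YRI	22	2.18	0.14	65.91	34.09	0	28.57	71.43	0.089
Sub-Saharan Africans	BAN	18	2.66	0.10	72.22	27.78	0	50.00	50.00	0
North-African/Middle East	ALG	26	0.04	0.84	32.69	67.31	0	21.43	78.57	0.256
North-African/Middle East	BED	36	0.47	0.49	47.22	52.78	14.63	53.66	31.71	0.772
North-African/Middle East	DRU	37	1.87	0.17	36.49	63.51	9.09	56.82	34.09	1
North-African/Middle East	PAL	40	0.44	0.50	31.25	68.75	4.44	44.44	51.11	0.936
European	FRA	27	1.47	0.23	40.74	59.26	16.67	41.67	41.67	1
European	BASQ	21	1.70	0.19	40.48	59.52	9.09	54.55	36.36	0.91
European	SARD	24	0	0.97	29.17	70.83	13.04	47.83	39.13	1
European	ITL	17	0.28	0.60	31.76	38.24	35.00	40.00	25.00	1
European	ORC	16	2.80	0.09	31.25	68.75	23.08	23.08	53.85	1
European	RUS	23	0.18	0.68	39.13	60.87	14.29	42.86	42.86	0.897
Central-South Asians	BRA	22	0.61	0.44	43.18	56.82	21.74	43.48	34.78	1
Central-South Asians	BAL	18	0.21	0.65	27.78	72.22	5.00	40.00	55.00	0.852
Central-South Asians	MAK	24	0.67	0.41	50.00	50.00	23.81	42.86	33.33	0.55
Central-South Asians	SIN	21	1.71	0.19	33.33	66.67	0	50.00	50.00	0.905
Central-South Asians	KAL	24	1.53	0.22	47.92	52.08	16.67	55.56	27.78	0.861
Central-South Asians	BUR	23	3.19	0.07	41.30	58.70	27.27	31.82	40.91	1
Central-South Asians	HAZ	17	1.14	0.29	79.41	20.59	43.75	56.25	0	0.904
Eastern Asians	CHB	34	0	0.98	38.24	61.76	0	52.17	47.83	0.468
Eastern Asians	JPN	26	2.45	0.12	48.08	51.92	50.00	37.93	37.93	0.837
Eastern Asians	YAK	11	0.55	0.46	77.27	22.73	50.00	31.82	18.18	1
Eastern Asians	NEA	34	0.54	0.46	45.59	54.41	20.59	52.94	26.47	0.852
Eastern Asians	SEA	36	0.73	0.40	29.17	70.83	5.88	50.00	44.12	0.537
Oceania	OCE	35	2.31	0.13	50.00	50.00	26.47	41.18	32.35	0.935
Americans	PIMA	22	0.51	0.48	25.00	75.00	9.09	36.36	54.55	0.804
Americans	MAYA	21	0.94	0.33	38.10	61.90	7.14	57.14	35.71	1
Americans	KAR	17	0.02	0.90	97.06	2.94	90.48	4.76	4.76	1
Americans	SUR	15	1.52	0.22	26.67	73.33	10.53	26.31	63.16	1
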