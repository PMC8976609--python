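gene	bin	n_carriers	region	start	end	ror	ci_low	ci_high	p_raw	p_fdr
BRCA1	1	58		34	335	0.81	0.45	1.47	0.49	0.63
BRCA1	2	58		397	1115	0.78	0.44	1.41	0.4126	0.6189
BRCA1	3	63	OCCR1	1154	2111	0.29	0.15	0.57	0.0001539	0.0012186
BRCA1	4	58		2127	3229	1.07	0.61	1.89	0.8066	0.8066
BRCA1	5	62		3257	3771	0.78	0.44	1.37	0.3852	0.6189
BRCA1	6	59		3841	4573	0.88	0.48	1.60	0.6704	0.7542
BRCA1	7	58		4609	5095	1.65	0.92	2.97	0.09114	0.27342
BRCA1	8	59		5096	5468-1	1.46	0.80	2.66	0.2158	0.48555
BRCA1	9	66	BCCR1	5470	5524	3.12	1.65	5.88	0.0002708	0.0012186
BRCA2	1	41	BCCR2	10	2176	3.47	1.51	7.96	0.002485	0.012425
BRCA2	2	41		2244	4038	1.00	0.47	2.14	0.9981	0.9981
BRCA2	3	48		4151	5723	0.49	0.23	1.04	0.0603	0.1005
BRCA2	4	41	OCCR2	5745	7805+1	0.38	0.16	0.86	0.01789	0.044725
BRCA2	5	40		7835	10150	1.63	0.73	3.62	0.2281	0.285125
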