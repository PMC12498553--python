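time_h	group	atp_mean	atp_sd	lc3_ratio_mean	lc3_ratio_sd	p62_mean	p62_sd	ampk_mean	ampk_sd	sirt1_mean	sirt1_sd
units	label	umol/L	umol/L	ratio	ratio	ng/mg	ng/mg	relative	relative	TPM	TPM
0	A	20.1	1.2	0.05	0.01	0.08	0.02	0.85	0.05	4.2	0.3
0	D	16.3	1.5	0.15	0.02	0.03	0.01	1.42	0.08	6.8	0.5
24	A	19.8	1.0	0.06	0.01	0.07	0.02	0.88	0.04	4.3	0.4
24	D	18.7	1.3	0.12	0.02	0.04	0.01	1.21	0.06	5.9	0.4
72	A	20.3	1.1	0.05	0.01	0.08	0.02	0.86	0.05	4.1	0.3
72	D	19.5	1.4	0.08	0.01	0.06	0.02	0.98	0.07	4.7	0.4
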