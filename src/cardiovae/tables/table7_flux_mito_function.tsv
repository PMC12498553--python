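group	p62_degradation_rate	atg5_expression	ocr	ecar	membrane_potential
units	percent	relative	pmol/min	mpH/min	mV
A	9.8	1	148.3	19.6	-121.4
B	24.7	1.28	179.5	24.3	-110.7
C	39.2	1.57	208.9	29.8	-101.2
D	54.6	1.83	247.6	34.7	-91.8
E	29.5	1.39	187.3	27.5	-114.3
F	48.9	1.68	228.4	32.1	-96.5
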