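group	ATP	ADP	AMP	NADH	NAD+	NADP
units	umol/L	umol/L	umol/L	umol/L	umol/L	umol/L
A	20	15	5	25	20	10
B	22	14	6	23	21	11
C	25	12	7	20	22	12
D	27	10	8	18	25	13
E	24	13	6	22	23	11
F	26	11	7	21	24	12
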