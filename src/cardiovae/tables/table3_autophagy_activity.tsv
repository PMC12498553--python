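group	lc3ii_lc3i_ratio	p62_expression
units	ratio	relative
A	0.05	0.08
B	0.08	0.06
C	0.12	0.04
D	0.15	0.03
E	0.10	0.05
F	0.14	0.02
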