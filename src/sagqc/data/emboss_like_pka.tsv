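group	pka	polarity
Nterm	8.6	base
Cterm	3.6	acid
C	8.5	acid
D	3.9	acid
E	4.1	acid
H	6.5	base
K	10.8	base
R	12.5	base
Y	10.1	acid
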