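# Default pKa set (standard biochemistry textbook values).
group	pka
D	3.65
E	4.25
H	6.0
C	8.3
Y	10.1
K	10.5
R	12.5
NTERM	9.0
CTERM	2.0
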