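# Guy (1985) side-chain partition energies (kcal/mol); positive = hydrophilic.
# His is transcribed as +0.50 (hydrophilic, grouped with the other ionizable
# residues); some electronic reproductions print -0.50 instead.
# higher_is_hydrophobic: false
residue	neutral
A	0.10
C	-1.42
D	0.78
E	0.83
F	-2.12
G	0.33
H	0.50
I	-1.13
K	1.40
L	-1.18
M	-1.59
N	0.48
P	0.73
Q	0.95
R	1.91
S	0.52
T	0.07
V	-1.27
W	-0.51
Y	-0.21
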