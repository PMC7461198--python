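# Default two-state pH-dependent hydropathy scale.
# neutral column: Kyte-Doolittle values for the uncharged species.
# charged column: hydropathy of the ionized species for the seven titratable
# side chains (D, E, H, C, Y, K, R), set to -5.0 (strongly hydrophilic, just
# below the Kyte-Doolittle minimum). Non-ionizable residues have
# charged == neutral. Per-residue values at a given pH are the
# Henderson-Hasselbalch population-weighted mixture of the two species.
# higher_is_hydrophobic: true
residue	neutral	charged
A	1.8	1.8
C	2.5	-5.0
D	-3.5	-5.0
E	-3.5	-5.0
F	2.8	2.8
G	-0.4	-0.4
H	-3.2	-5.0
I	4.5	4.5
K	-3.9	-5.0
L	3.8	3.8
M	1.9	1.9
N	-3.5	-3.5
P	-1.6	-1.6
Q	-3.5	-3.5
R	-4.5	-5.0
S	-0.8	-0.8
T	-0.7	-0.7
V	4.2	4.2
W	-0.9	-0.9
Y	-1.3	-5.0
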