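# SYNTHETIC stand-in for the IDP-Hydropathy scale (Huang et al. 2014), whose
# exact constants are not redistributable here. Built as the mean of the
# normalized Guy and Kyte-Doolittle scales with Pro forced to be the single
# most hydrophilic residue (normalized value 0), the one property of the
# original scale that is documented. Correlations computed against this file
# do NOT reproduce the original scale's published correlations.
# higher_is_hydrophobic: true
residue	neutral
A	0.654
C	0.892
D	0.257
E	0.251
F	1.000
G	0.496
H	0.311
I	0.970
K	0.153
L	0.936
M	0.879
N	0.296
P	0.000
Q	0.235
R	0.052
S	0.448
T	0.512
V	0.971
W	0.576
Y	0.514
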