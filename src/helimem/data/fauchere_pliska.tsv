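# Fauchere & Pliska (1983) side-chain hydrophobicity scale, pi = log P
# (N-acetyl amino-acid amide octanol/water partition), dimensionless.
# Standard published values; used as per-residue hydrophobic weights.
residue	weight
A	0.31
R	-1.01
N	-0.60
D	-0.77
C	1.54
Q	-0.22
E	-0.64
G	0.00
H	0.13
I	1.80
L	1.70
K	-0.99
M	1.23
F	1.79
P	0.72
S	-0.04
T	0.26
W	2.25
Y	0.96
V	1.22
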