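# GES (Goldman-Engelman-Steitz) transfer free energies, kcal/mol.
# Oriented so that hydrophobic residues score positive (water -> bilayer
# favourable), matching hydropathy plots that cross 0 at the membrane edge.
# v1
F	3.7
M	3.4
I	3.1
L	2.8
V	2.6
C	2.0
W	1.9
A	1.6
T	1.2
G	1.0
S	0.6
P	-0.2
Y	-0.7
H	-3.0
Q	-4.1
N	-4.8
E	-8.2
K	-8.8
D	-9.2
R	-12.3
X	0.0
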