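# name: ww_interface
# unit: kcal/mol
# sign_convention: whole-residue free energy of transfer from water to the POPC bilayer interface; favourable partitioning negative
# source: Wimley & White, Nat Struct Biol 3:842 (1996), whole-residue interface scale; charged side-chain values for D and E, neutral H
# residue	value
A	0.17
C	-0.24
D	1.23
E	2.02
F	-1.13
G	0.01
H	0.17
I	-0.31
K	0.99
L	-0.56
M	-0.23
N	0.42
P	0.45
Q	0.58
R	0.81
S	0.13
T	0.14
V	0.07
W	-1.85
Y	-0.94
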