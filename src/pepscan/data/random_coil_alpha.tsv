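# name: random_coil_alpha
# unit: ppm
# sign_convention: alpha-proton chemical shift of the residue in an unstructured (random coil) peptide
# source: Wuthrich, NMR of Proteins and Nucleic Acids, Wiley (1986), Table 2.3 (GGXA peptides in water)
# residue	value
A	4.35
C	4.69
D	4.76
E	4.29
F	4.66
G	3.97
H	4.63
I	4.23
K	4.36
L	4.38
M	4.52
N	4.75
P	4.44
Q	4.37
R	4.38
S	4.50
T	4.35
V	4.18
W	4.70
Y	4.60
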