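# Assigned proton chemical shifts of MTP1 (KVSGVLFGTGLWVAL-NH2) in DMSO-d6 at 298 K.
# Referenced to the DMSO residual signal (2.5 ppm). Side-chain 'Others' resonances omitted.
# Glycine diastereotopic alpha-proton pairs are stored as their mean in a single aCH record.
residue_index	residue	atom	shift_ppm	note
1	LYS	aCH	3.51
1	LYS	bCH	1.63
1	LYS	gCH	1.34
2	VAL	NH	8.18
2	VAL	aCH	4.28
2	VAL	bCH	2.02
2	VAL	gCH	0.84
3	SER	NH	8.11
3	SER	aCH	4.30
3	SER	bCH	3.57
4	GLY	NH	8.06
4	GLY	aCH	3.775	mean of 3.81/3.74
5	VAL	NH	7.76
5	VAL	aCH	4.19
5	VAL	bCH	1.91
5	VAL	gCH	0.74
6	LEU	NH	7.98
6	LEU	aCH	4.26
6	LEU	bCH	1.36
6	LEU	gCH	1.49
7	PHE	NH	7.92
7	PHE	aCH	4.53
7	PHE	bCH	3.02
7	PHE	bCH	2.84
8	GLY	NH	8.24
8	GLY	aCH	3.81
9	THR	NH	7.81
9	THR	aCH	4.21
9	THR	bCH	4.08
10	GLY	NH	8.08
10	GLY	aCH	3.76	mean of 3.81/3.71
11	LEU	NH	7.87
11	LEU	aCH	4.33
11	LEU	bCH	1.39
11	LEU	gCH	1.51
12	TRP	NH	8.13
12	TRP	aCH	4.56
12	TRP	bCH	3.14
12	TRP	bCH	2.96
13	VAL	NH	7.72
13	VAL	aCH	4.18
13	VAL	bCH	1.94
13	VAL	gCH	0.83
14	ALA	NH	8.02
14	ALA	aCH	4.29
14	ALA	bCH	1.19
15	LEU	NH	7.72
15	LEU	aCH	4.18
15	LEU	bCH	1.43
15	LEU	gCH	1.58
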