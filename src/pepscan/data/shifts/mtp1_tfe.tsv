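# Assigned proton chemical shifts of MTP1 (KVSGVLFGTGLWVAL-NH2) in TFE-d3:H2O 1:1 at 298 K.
# Referenced to internal TSP. Side-chain 'Others' resonances omitted.
# Glycine diastereotopic alpha-proton pairs are stored as their mean in a single aCH record.
residue_index	residue	atom	shift_ppm	note
1	LYS	aCH	4.11
1	LYS	bCH	1.98
1	LYS	gCH	1.51
2	VAL	NH	8.45
2	VAL	aCH	4.25
2	VAL	bCH	2.12
2	VAL	gCH	1.01
3	SER	NH	8.16
3	SER	aCH	4.55
3	SER	bCH	3.95
3	SER	bCH	3.88
4	GLY	NH	8.24
4	GLY	aCH	4.02
5	VAL	NH	7.76
5	VAL	aCH	4.12
5	VAL	bCH	2.08
5	VAL	gCH	0.95
6	LEU	NH	7.84
6	LEU	aCH	4.34
6	LEU	bCH	1.62
6	LEU	gCH	1.51
7	PHE	NH	7.78
7	PHE	aCH	4.34
7	PHE	bCH	3.10
7	PHE	bCH	3.01
8	GLY	NH	7.80
8	GLY	aCH	3.88	mean of 3.98/3.78
9	THR	NH	7.79
9	THR	aCH	4.36
9	THR	bCH	4.36
10	GLY	NH	8.11
10	GLY	aCH	3.885	mean of 3.91/3.86
11	LEU	NH	7.74
11	LEU	aCH	4.21
11	LEU	bCH	1.59
11	LEU	gCH	1.59
12	TRP	NH	7.60
12	TRP	aCH	4.43
12	TRP	bCH	3.35	single value reported
13	VAL	NH	7.40
13	VAL	aCH	3.72
13	VAL	bCH	2.00
13	VAL	gCH	0.85
14	ALA	NH	7.69
14	ALA	aCH	4.22
14	ALA	bCH	1.45
15	LEU	NH	7.80
15	LEU	aCH	4.30
15	LEU	bCH	1.78
15	LEU	gCH	1.62
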