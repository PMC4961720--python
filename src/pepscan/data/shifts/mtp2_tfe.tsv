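# Assigned proton chemical shifts of MTP2 (MAEAHQAKAFQDT-NH2) in H2O/TFE-d3 1:1 at 298 K.
# Referenced to internal TSP. Side-chain 'Others' resonances omitted.
residue_index	residue	atom	shift_ppm	note
1	MET	aCH	4.16
1	MET	bCH	2.24
1	MET	gCH	2.68
2	ALA	NH	8.61
2	ALA	aCH	4.43
2	ALA	bCH	1.45
3	GLU	NH	8.36
3	GLU	aCH	4.37
3	GLU	bCH	2.13
3	GLU	bCH	2.00
3	GLU	gCH	2.47
4	ALA	NH	8.20
4	ALA	aCH	4.29
4	ALA	bCH	1.39
5	HIS	NH	8.36
5	HIS	aCH	4.67
5	HIS	bCH	3.33
5	HIS	bCH	3.24
6	GLN	NH	8.31
6	GLN	aCH	4.36
6	GLN	bCH	2.15
6	GLN	bCH	2.05
6	GLN	gCH	2.39
7	ALA	NH	8.24
7	ALA	aCH	4.33
7	ALA	bCH	1.45
8	LYS	NH	8.04
8	LYS	aCH	4.30
8	LYS	bCH	1.84
8	LYS	gCH	1.48
9	ALA	NH	8.02
9	ALA	aCH	4.27
9	ALA	bCH	1.34
10	PHE	NH	7.90
10	PHE	aCH	4.58
10	PHE	bCH	3.21
10	PHE	bCH	3.12
11	GLN	NH	8.11
11	GLN	aCH	4.33
11	GLN	bCH	2.14
11	GLN	bCH	2.05
11	GLN	gCH	2.36
12	ASP	NH	8.30
12	ASP	aCH	4.78
12	ASP	bCH	2.97
12	ASP	bCH	2.86
13	THR	NH	7.93
13	THR	aCH	4.34
13	THR	bCH	4.34
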