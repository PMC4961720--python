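# Assigned proton chemical shifts of MTP2 (MAEAHQAKAFQDT-NH2) in DMSO-d6 at 298 K.
# Referenced to the DMSO residual signal (2.5 ppm). Side-chain 'Others' resonances omitted.
residue_index	residue	atom	shift_ppm	note
1	MET	aCH	3.84
1	MET	bCH	1.96
1	MET	gCH	2.51
2	ALA	NH	8.62
2	ALA	aCH	4.37
2	ALA	bCH	1.24
3	GLU	NH	8.15
3	GLU	aCH	4.27
3	GLU	bCH	1.89
3	GLU	bCH	1.73
3	GLU	gCH	2.25
4	ALA	NH	7.88
4	ALA	aCH	4.19
4	ALA	bCH	1.16
5	HIS	NH	8.12
5	HIS	aCH	4.45
5	HIS	bCH	2.91
6	GLN	NH	8.03
6	GLN	aCH	4.17
6	GLN	bCH	1.87
6	GLN	bCH	1.72
6	GLN	gCH	2.08
7	ALA	NH	8.38
7	ALA	aCH	4.25
7	ALA	bCH	1.21
8	LYS	NH	7.90
8	LYS	aCH	4.19
8	LYS	bCH	1.62
8	LYS	gCH	1.28
9	ALA	NH	8.08
9	ALA	aCH	4.25
9	ALA	bCH	1.19
10	PHE	NH	7.94
10	PHE	aCH	4.47
10	PHE	bCH	3.04
10	PHE	bCH	2.81
11	GLN	NH	8.09
11	GLN	aCH	4.24
11	GLN	bCH	1.84
11	GLN	bCH	1.77
11	GLN	gCH	2.10
12	ASP	NH	8.33
12	ASP	aCH	4.62
12	ASP	bCH	2.74
12	ASP	bCH	2.56
13	THR	NH	7.51
13	THR	aCH	4.86
13	THR	bCH	4.06
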