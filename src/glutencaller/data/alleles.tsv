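name	variant	locus	subunit_type	cysteine_count	display	predicted_mass	accession	notes
1Ax1		Glu-A1	x	4	1	87679	X61009
1Ax2*		Glu-A1	x	4	2*	86335	M22208	near-isobaric with 1Bx6; RP-HPLC separates them
1Bx6		Glu-B1	x	4	6	86523	KX454509	near-isobaric with 1Ax2*; RP-HPLC separates them
1Bx7	group1	Glu-B1	x	4	7	82527	X13927	lower-mass 1Bx7 class, ~82,400 Da after adduct correction
1Bx7	group2	Glu-B1	x	4	7	82527	X13927	higher-mass 1Bx7 class, ~83,000 Da after adduct correction; 18 bp coding insertion, single gene copy
1Bx7	OE	Glu-B1	x	4	7OE	83122	EU157184	overexpressed 1Bx7; gene duplication detectable only by PCR, mass-identical to group 2
1Bx13		Glu-B1	x	4	13	83209	EF540764	tightly linked to 1By16
1Bx14		Glu-B1	x	4	14	82343	KF733216	tightly linked to 1By15
1Bx17		Glu-B1	x	4	17	77960	AB263219	tightly linked to 1By18
1Bx20		Glu-B1	x	2	20	83895	AJ437000	2 cysteine residues; tightly linked to 1By20
1By8		Glu-B1	y	7	8	75159	AY245797	near-isobaric with 1By8*; RP-HPLC separates them
1By8*		Glu-B1	y	7	8*			no public gene sequence; near-isobaric with 1By8
1By9		Glu-B1	y	7	9	73517	X61026
1By15		Glu-B1	y	7	15	74738	KF733215	identified via linked 1Bx14
1By16		Glu-B1	y	7	16	77283	EF540765	identified via linked 1Bx13
1By18		Glu-B1	y	7	18	75187	KF430649	identified via linked 1Bx17
1By20		Glu-B1	y	7	20	75148	LN828972	identified via linked 1Bx20
1Dx2		Glu-D1	x	4	2	87007	X03346
1Dx2.2		Glu-D1	x	4	2.2	100886	AY159367	heaviest subunit, near the upper end of the acquisition range
1Dx4		Glu-D1	x	4	4			no public gene sequence
1Dx5		Glu-D1	x	5	5	88126	X12928	5 cysteine residues
1Dy10		Glu-D1	y	7	10	67475	X12929
1Dy12		Glu-D1	y	7	12	68713	X03041
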