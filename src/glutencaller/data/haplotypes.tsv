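locus	label	x_allele	y_allele	searchable
Glu-A1	1	1Ax1		true
Glu-A1	2*	1Ax2*		true
Glu-A1	N			true
Glu-B1	6+8*	1Bx6	1By8*	true
Glu-B1	7+8	1Bx7	1By8	true
Glu-B1	7+8*	1Bx7	1By8*	true
Glu-B1	7+9	1Bx7	1By9	true
Glu-B1	7	1Bx7		true
Glu-B1	7OE+8*	1Bx7:OE	1By8*	false
Glu-B1	13+16	1Bx13	1By16	true
Glu-B1	14+15	1Bx14	1By15	true
Glu-B1	17+18	1Bx17	1By18	true
Glu-B1	20+20	1Bx20	1By20	true
Glu-D1	2+12	1Dx2	1Dy12	true
Glu-D1	2.2+12	1Dx2.2	1Dy12	true
Glu-D1	4+12	1Dx4	1Dy12	true
Glu-D1	5+10	1Dx5	1Dy10	true
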