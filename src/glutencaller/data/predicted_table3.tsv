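allele	variant	accession	predicted_mass	cultivar	corrected_mass	difference	error_pct
1Ax1		X61009	87679	Hanno	87565	-114	-0.13
1Ax1		X61009	87679	Imbros	87481	-198	-0.23
1Ax1		X61009	87679	Insignia	87561	-118	-0.13
1Ax1		X61009	87679	Nanbu-Komugi	87472	-207	-0.24
1Ax1		X61009	87679	Orepi	87528	-151	-0.17
1Ax1		X61009	87679	IT166460	87488	-191	-0.22
1Ax2*		M22208	86335	Cheyenne	86135	-200	-0.23
1Ax2*		M22208	86335	Glenlea	86170	-165	-0.19
1Ax2*		M22208	86335	Magnif 27	86240	-95	-0.11
1Ax2*		M22208	86335	Neepawa	86187	-148	-0.17
1Ax2*		M22208	86335	Norin 61	86151	-184	-0.21
1Ax2*		M22208	86335	Opata	86134	-201	-0.23
1Ax2*		M22208	86335	Soissons	86180	-155	-0.18
1Ax2*		M22208	86335	Sukang	86202	-133	-0.15
1Ax2*		M22208	86335	Manital	86177	-158	-0.18
1Ax2*		M22208	86335	Baekjoong	86150	-185	-0.21
1Bx6		KX454509	86523	Brimstone	86419	-104	-0.12
1Bx6		KX454509	86523	Clement	86407	-116	-0.13
1Bx6		KX454509	86523	Thesee	86440	-83	-0.10
1Bx7	group1	X13927	82527	Apexal	82410	-117	-0.14
1Bx7	group1	X13927	82527	Cheyenne	82403	-124	-0.15
1Bx7	group1	X13927	82527	Neepawa	82460	-67	-0.08
1Bx7	group1	X13927	82527	Norin 61	82421	-106	-0.13
1Bx7	group1	X13927	82527	Orca	82402	-125	-0.15
1Bx7	group1	X13927	82527	Soissons	82382	-145	-0.18
1Bx7	group2	X13927	82527	Cappelle-Desprez	82995	468	0.57
1Bx7	group2	X13927	82527	Chinese Spring	83067	540	0.65
1Bx7	group2	X13927	82527	Nanbu-Komugi	83016	489	0.59
1Bx7	group2	X13927	82527	Orepi	83062	535	0.65
1Bx7	group2	X13927	82527	Petrel	82984	457	0.55
1Bx7	OE	EU157184	83122	Glenlea	82981	-141	-0.17
1Bx7	OE	EU157184	83122	IT166460	83113	-9	-0.01
1Bx13		EF540764	83209	Magnif 27	83054	-155	-0.19
1Bx13		EF540764	83209	Opata	83045	-164	-0.20
1Bx13		EF540764	83209	Sukang	83027	-182	-0.22
1Bx13		EF540764	83209	Baekjoong	83059	-150	-0.18
1Bx14		KF733216	82343	Hanno	82365	22	0.03
1Bx14		KF733216	82343	Imbros	82346	3	0.00
1Bx17		AB263219	77960	Manital	78606	646	0.83
1Bx20		AJ437000	83895	Insignia	83803	-92	-0.11
1By8		AY245797	75159	Chinese Spring	75150	-9	-0.01
1By8		AY245797	75159	Nanbu-Komugi	75140	-19	-0.03
1By8		AY245797	75159	Norin 61	75133	-26	-0.03
1By8		AY245797	75159	Soissons	75133	-26	-0.03
1By8*				Brimstone	75257		
1By8*				Clement	75245		
1By8*				Glenlea	75142		
1By8*				Thesee	75281		
1By8*				IT166460	75225		
1By9		X61026	73517	Apexal	73528	11	0.01
1By9		X61026	73517	Cheyenne	73559	42	0.06
1By9		X61026	73517	Neepawa	73538	21	0.03
1By15		KF733215	74738	Hanno	74790	52	0.07
1By15		KF733215	74738	Imbros	74816	78	0.10
1By16		EF540765	77283	Magnif 27	77054	-229	-0.30
1By16		EF540765	77283	Opata	77088	-195	-0.25
1By16		EF540765	77283	Sukang	77058	-225	-0.29
1By16		EF540765	77283	Baekjoong	77055	-228	-0.29
1By18		KF430649	75187	Manital	75224	37	0.05
1By20		LN828972	75148	Insignia	75123	-25	-0.03
1Dx2		X03346	87007	Brimstone	87010	3	0.00
1Dx2		X03346	87007	Cappelle-Desprez	86943	-64	-0.07
1Dx2		X03346	87007	Chinese Spring	87072	65	0.07
1Dx2		X03346	87007	Clement	86958	-49	-0.06
1Dx2		X03346	87007	Imbros	87002	-5	-0.01
1Dx2		X03346	87007	Magnif 27	86992	-15	-0.02
1Dx2		X03346	87007	Opata	86950	-57	-0.07
1Dx2		X03346	87007	Orca	86910	-97	-0.11
1Dx2		X03346	87007	Thesee	86960	-47	-0.05
1Dx2		X03346	87007	Sukang	86949	-58	-0.07
1Dx2		X03346	87007	Manital	86928	-79	-0.09
1Dx2		X03346	87007	IT166460	87029	22	0.03
1Dx2.2		AY159367	100886	Norin 61	100390	-496	-0.49
1Dx2.2		AY159367	100886	Baekjoong	100388	-498	-0.49
1Dx4				Nanbu-Komugi	85452		
1Dx4				Orepi	85959		
1Dx5		X12928	88126	Apexal	87932	-194	-0.22
1Dx5		X12928	88126	Cheyenne	87924	-202	-0.23
1Dx5		X12928	88126	Glenlea	87951	-175	-0.20
1Dx5		X12928	88126	Hanno	87933	-193	-0.22
1Dx5		X12928	88126	Insignia	87920	-206	-0.23
1Dx5		X12928	88126	Neepawa	87980	-146	-0.17
1Dx5		X12928	88126	Petrel	87906	-220	-0.25
1Dx5		X12928	88126	Soissons	87931	-195	-0.22
1Dy10		X12929	67475	Apexal	67652	177	0.26
1Dy10		X12929	67475	Cheyenne	67664	189	0.28
1Dy10		X12929	67475	Glenlea	67617	142	0.21
1Dy10		X12929	67475	Hanno	67610	135	0.20
1Dy10		X12929	67475	Insignia	67647	172	0.25
1Dy10		X12929	67475	Neepawa	67652	177	0.26
1Dy10		X12929	67475	Petrel	67603	128	0.19
1Dy10		X12929	67475	Soissons	67601	126	0.19
1Dy12		X03041	68713	Brimstone	68668	-45	-0.07
1Dy12		X03041	68713	Cappelle-Desprez	68654	-59	-0.09
1Dy12		X03041	68713	Chinese Spring	68674	-39	-0.06
1Dy12		X03041	68713	Clement	68678	-35	-0.05
1Dy12		X03041	68713	Imbros	68668	-45	-0.07
1Dy12		X03041	68713	Magnif 27	68673	-40	-0.06
1Dy12		X03041	68713	Nanbu-Komugi	68637	-76	-0.11
1Dy12		X03041	68713	Norin 61	68626	-87	-0.13
1Dy12		X03041	68713	Opata	68689	-24	-0.03
1Dy12		X03041	68713	Orca	68657	-56	-0.08
1Dy12		X03041	68713	Orepi	68697	-16	-0.02
1Dy12		X03041	68713	Thesee	68703	-10	-0.01
1Dy12		X03041	68713	Sukang	68686	-27	-0.04
1Dy12		X03041	68713	Manital	68645	-68	-0.10
1Dy12		X03041	68713	Baekjoong	68708	-5	-0.01
1Dy12		X03041	68713	IT166460	68717	4	0.01
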