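cultivar	glu_a1	glu_b1	glu_d1	bx7_group	bx7_dup_pcr	a1x_mass	b1x_mass	b1y_mass	d1x_mass	d1y_mass	a1x_rsd	b1x_rsd	b1y_rsd	d1x_rsd	d1y_rsd
Apexal	N	7+9	5+10	group1	false		82831	74264	88458	68388		0.036	0.054	0.050	0.032
Brimstone	N	6+8*	2+12				86840	75993	87431	69404		0.076	0.083	0.014	0.071
Cappelle-Desprez	N	7	2+12	group2	false		83416		87364	69390		0.072		0.050	0.054
Cheyenne	2*	7+9	5+10	group1	false	86556	82824	74295	88450	68400	0.036	0.076	0.059	0.078	0.073
Chinese Spring	N	7+8	2+12	group2	false		83488	75886	87493	69410		0.013	0.025	0.020	0.009
Clement	N	6+8*	2+12				86828	75981	87379	69414		0.091	0.066	0.037	0.069
Glenlea	2*	7OE+8*	5+10	OE	true	86591	83402	75878	88477	68353	0.025	0.068	0.050	0.031	0.034
Hanno	1	14+15	5+10			87986	82786	75526	88459	68346	0.030	0.039	0.035	0.068	0.021
Imbros	1	14+15	2+12			87902	82767	75552	87423	69404	0.039	0.035	0.033	0.025	0.037
Insignia	1	20+20	5+10			87982	84014	75859	88446	68383	0.015	0.078	0.057	0.063	0.068
Magnif 27	2*	13+16	2+12			86661	83475	77790	87413	69409	0.071	0.061	0.084	0.081	0.070
Nanbu-Komugi	1	7+8	4+12	group2	false	87893	83437	75876	85873	69393	0.060	0.022	0.030	0.062	0.043
Neepawa	2*	7+9	5+10	group1	false	86608	82881	74274	88506	68388	0.068	0.028	0.044	0.055	0.072
Norin 61	2*	7+8	2.2+12	group1	false	86572	82842	75869	100811	69362	0.042	0.067	0.077	0.044	0.065
Opata	2*	13+16	2+12			86555	83466	77824	87371	69425	0.036	0.055	0.072	0.076	0.025
Orca	N	7	2+12	group1	false		82823		87331	69393		0.055		0.068	0.030
Orepi	1	7	4+12	group2	false	87949	83483		86380	69433	0.044	0.031		0.066	0.045
Petrel	N	7	5+10	group2	false		83405		88432	68339		0.052		0.020	0.078
Soissons	2*	7+8	5+10	group1	false	86601	82803	75865	88457	68337	0.048	0.069	0.059	0.032	0.074
Thesee	N	6+8*	2+12				86861	76017	87381	69439		0.048	0.046	0.046	0.036
Sukang	2*	13+16	2+12			86623	83448	77794	87370	69422	0.092	0.058	0.044	0.053	0.088
Manital	2*	17+18	2+12			86598	79027	75960	87349	69381	0.058	0.036	0.050	0.046	0.070
Baekjoong	2*	13+16	2.2+12			86571	83480	77791	100809	69444	0.079	0.057	0.052	0.063	0.056
IT166460	1	7OE+8*	2+12	OE	true	87909	83534	75961	87450	69453	0.037	0.018	0.039	0.030	0.019
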