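cultivar	glu_a1	glu_b1	glu_d1	bx7_group	bx7_dup_pcr	a1x_mass	b1x_mass	b1y_mass	d1x_mass	d1y_mass	a1x_rsd	b1x_rsd	b1y_rsd	d1x_rsd	d1y_rsd
Alchan	2*	7+8	5+10	group2	false	86618	83457	75924	88493	68402	0.018	0.036	0.039	0.028	0.040
Anbaek	N	7+9	2+12	group1	false		82885	74323	87424	69452		0.037	0.032	0.024	0.035
Baekchal	2*	7+8*	5+10	group1	false	86606	82859	75874	88475	68416	0.021	0.027	0.048	0.023	0.053
Baekjoong	2*	13+16	2.2+12			86595	83478	77808	100834	69443	0.026	0.060	0.096	0.026	0.093
Chungkye	N	7+8	2.2+12	group1	false		82905	75907	100854	69427		0.034	0.016	0.013	0.053
Dabun	2*	7+8	2.2+12	group2	false	86582	83437	75889	100834	69402	0.031	0.034	0.019	0.019	0.039
Dahong	N	7+8	2.2+12	group2	false		83444	75907	100821	69415		0.033	0.031	0.017	0.080
Dajoong	2*	13+16	2.2+12			86634	83505	77858	100834	69456	0.025	0.040	0.054	0.015	0.046
Eunpa	N	7+9	2.2+12	group1	false		82851	74312	100855	69415		0.039	0.077	0.032	0.047
Geuru	N	7+8	2.2+12	group2	false		83445	75884	100828	69417		0.032	0.037	0.031	0.039
Gobun	N	7+9	2+12	group1	false		82903	74353	87427	69427		0.042	0.021	0.022	0.054
Goso	2*	7+8	2.2+12	group2	false	86601	83429	75922	100838	69467	0.017	0.035	0.045	0.033	0.025
Hanbaek	2*	7+8	5+10	group2	false	86661	83492	75922	88491	68408	0.047	0.030	0.038	0.048	0.052
Hojoong	2*	7+8	2.2+12	group1	false	86631	82886	75926	100830	69445	0.054	0.046	0.011	0.015	0.045
Jeokjoong	2*	13+16	2.2+12			86659	83488	77826	100826	69447	0.056	0.055	0.073	0.033	0.081
Jinpoom	N	7+8	2.2+12	group1	false		82907	75926	100842	69449		0.035	0.031	0.024	0.029
Joa	2*	7+8	2.2+12	group1	false	86617	82913	75932	100852	69462	0.032	0.053	0.036	0.020	0.046
Joeun	N	13+16	2.2+12				83505	77876	100835	69447		0.032	0.045	0.028	0.043
Jojoong	N	13+16	2.2+12				83504	77858	100836	69446		0.033	0.038	0.018	0.039
Jokyung	1	7+8	5+10	group2	false	87970	83433	75902	88473	68361	0.027	0.037	0.048	0.012	0.033
Jonong	N	7+9	2+12	group1	false		82874	74308	87421	69437		0.050	0.035	0.028	0.017
Joonmo2008	N	17+18	5+10				79062	75969	88480	68374		0.030	0.047	0.035	0.039
Joongmo2012	2*	7+8	5+10	group2	false	86632	83442	75896	88484	68411	0.044	0.041	0.046	0.022	0.050
Jopoom	N	13+16	2.2+12				83490	77858	100865	69440		0.044	0.064	0.024	0.038
Keumkang	2*	7+8	5+10	group2	false	86580	83448	75907	88500	68395	0.033	0.052	0.046	0.030	0.064
Milsung	N	7+8	2.2+12	group2	false		83448	75911	100857	69455		0.025	0.051	0.035	0.031
Namhae	N	7+8	2.2+12	group1	false		82909	75911	100848	69463		0.028	0.040	0.016	0.029
Ol	N	7+8	2.2+12	group1	false		82868	75883	100846	69426		0.028	0.021	0.037	0.037
Olgeuru	2*	7+8	2.2+12	group2	false	86672	83461	75927	100848	69458	0.031	0.031	0.060	0.022	0.040
Saeol	N	7+8	2.2+12	group2	false		83434	75924	100846	69441		0.042	0.069	0.029	0.043
Seodun	N	7+8	2.2+12	group1	false		82898	75936	100851	69451		0.056	0.018	0.023	0.045
Sinmichal	2*	7+8*	2.2+12	group1	false	86640	82877	75908	100852	69425	0.054	0.028	0.034	0.017	0.038
Sinmichal1	N	7+9	2+12	group1	false		82863	74328	87389	69424		0.042	0.031	0.042	0.053
Suan	2*	7+8	2.2+12	group1	false	86616	82858	75918	100853	69418	0.017	0.028	0.034	0.017	0.020
Sukang	2*	13+16	2+12			86660	83522	77831	87410	69420	0.020	0.033	0.033	0.034	0.015
Tapdong	2*	7+8	5+10	group1	false	86628	82884	75942	88503	68384	0.022	0.019	0.036	0.032	0.038
Uri	N	7+8	2.2+12	group2	false		83461	75923	100819	69438		0.035	0.036	0.025	0.053
Younbaek	2*	13+16	2.2+12			86644	83476	77861	100838	69433	0.024	0.026	0.046	0.023	0.055
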