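pair	np	ref	site_minor	carrier	gene	synonymous	aa_ref	aa_alt	slot	sample_code	major	major_fwd	major_rev	major_pct	minor	minor_fwd	minor_rev	minor_pct
1	2746	T	C	mother	16S				mother_buccal	693	T	2920	6014	79.67	C	655	1600	20.11
1	2746	T	C	mother	16S				child_buccal	677	T	4838	14038	99.64	C	1	9	0.053
1	2746	T	C	mother	16S				mother_blood	M207	T	14187	14328	80.3	C	3440	3528	19.62
1	2746	T	C	mother	16S				child_blood	M207-C	T	24044	24176	99.88	C	6	12	0.037
2	16320	C	T	mother	CR				mother_buccal	406	C	4918	3843	72.33	T	1866	1474	27.57
2	16320	C	T	mother	CR				child_buccal	444	C	17616	13273	99.92	T	9	7	0.052
2	16320	C	T	mother	CR				mother_blood	M137	C	5412	4619	94.9	T	288	248	5.07
2	16320	C	T	mother	CR				child_blood	M137-C	C	4232	3670	99.92	T	2	1	0.038
3	9179	T	C	mother	ATP6	N	Val	Ala	mother_buccal	1134	T	3063	5076	85.02	C	538	892	14.93
3	9179	T	C	mother	ATP6	N	Val	Ala	child_buccal	1099	T	6651	8730	99.82	C	8	7	0.097
3	9179	T	C	mother	ATP6	N	Val	Ala	mother_blood	M502G	T	16583	20269	87.14	C	2468	2934	12.77
3	9179	T	C	mother	ATP6	N	Val	Ala	child_blood	M501	T	38769	44060	99.81	C	32	24	0.067
4	14040	G	A	mother	ND5	Y	Gln	Gln	mother_buccal	659	G	5770	4227	92.01	A	474	381	7.86
4	14040	G	A	mother	ND5	Y	Gln	Gln	child_buccal	722	G	20789	16141	99.86	A	8	12	0.054
4	14040	G	A	mother	ND5	Y	Gln	Gln	mother_blood	M242	G	13200	12992	94.07	A	831	811	5.89
4	14040	G	A	mother	ND5	Y	Gln	Gln	child_blood	M242-C	G	10355	10087	99.88	A	5	5	0.049
5	14461	T	C	mother	ND6	Y	Thr	Thr	mother_buccal	411	T	7078	7720	97.04	C	205	233	2.87
5	14461	T	C	mother	ND6	Y	Thr	Thr	child_buccal	401	T	16084	15992	99.78	C	35	18	0.165
5	14461	T	C	mother	ND6	Y	Thr	Thr	mother_blood	M132	T	8475	8875	97.54	C	193	237	2.41
5	14461	T	C	mother	ND6	Y	Thr	Thr	child_blood	M132-C	T	5854	6622	99.92	C	8	1	0.072
6	11825	G	A	mother	ND4	N	Ala	Thr	mother_buccal	711	G	1622	2662	93.41	A	116	184	6.54
6	11825	G	A	mother	ND4	N	Ala	Thr	child_buccal	737	G	8943	15813	99.8	A	8	3	0.044
6	11825	G	A	mother	ND4	N	Ala	Thr	mother_blood	M203	G	4728	5871	97.1	A	133	167	2.74
6	11825	G	A	mother	ND4	N	Ala	Thr	child_blood	M203-C	G	14625	18730	99.88	A	6	5	0.033
6	12375	T	C	child	ND5	Y	Thr	Thr	mother_buccal	711	T	1713	1597	99.67	C	1	9	0.301
6	12375	T	C	child	ND5	Y	Thr	Thr	child_buccal	737	T	6368	6238	72.03	C	2770	2099	27.82
6	12375	T	C	child	ND5	Y	Thr	Thr	mother_blood	M203	T	4588	4190	99.66	C	13	12	0.284
6	12375	T	C	child	ND5	Y	Thr	Thr	child_blood	M203-C	T	10455	10132	76.0	C	3481	3008	23.95
7	13790	A	G	child	ND5	N	Tyr	Cys	mother_buccal	729	A	2539	943	99.63	G	1	1	0.057
7	13790	A	G	child	ND5	N	Tyr	Cys	child_buccal	684	A	5501	2427	88.46	G	650	356	11.22
7	13790	A	G	child	ND5	N	Tyr	Cys	mother_blood	M213	A	10487	7516	99.46	G	4	25	0.16
7	13790	A	G	child	ND5	N	Tyr	Cys	child_blood	M213-C	A	5900	4359	88.44	G	705	583	11.1
8	200	A	A	mother	CR				mother_buccal	1098	G	1350	3677	96.58	A	31	139	3.26
8	200	A	A	mother	CR				child_buccal	1100	G	1148	3998	98.79	A	5	54	1.13
8	200	A	A	mother	CR				mother_blood	M520	G	821	1294	97.6	A	17	32	2.26
8	200	A	A	mother	CR				child_blood	M520-C	G	5713	9174	99.59	A	14	41	0.368
9	4191	A	T	child	ND1	Y	Pro	Pro	mother_buccal	1122	A	8781	10930	99.36	T	2	27	0.146
9	4191	A	T	child	ND1	Y	Pro	Pro	child_buccal	1119	A	4452	5729	95.5	T	202	243	4.17
9	4191	A	T	child	ND1	Y	Pro	Pro	mother_blood	M500	A	5699	6469	99.37	T	3	25	0.229
9	4191	A	T	child	ND1	Y	Pro	Pro	child_blood	M500-C	A	12277	14284	94.96	T	612	695	4.67
10	16170	A	G	mother	CR				mother_buccal	1267	A	17593	21027	94.49	G	1060	1174	5.46
10	16170	A	G	mother	CR				child_buccal	1160	A	15700	21013	99.95	G	4	5	0.025
10	16170	A	G	mother	CR				mother_blood	SC16	A	8155	10691	96.19	G	332	413	3.8
10	16170	A	G	mother	CR				child_blood	SC16-C	A	10154	13352	99.97	G	1	2	0.013
11	9196	G	A	mother	ATP6	N	Asp	Asn	mother_buccal	839	G	6061	10535	97.36	A	172	265	2.56
11	9196	G	A	mother	ATP6	N	Asp	Asn	child_buccal	1189	G	4644	7284	99.81	A	0	6	0.05
11	9196	G	A	mother	ATP6	N	Asp	Asn	mother_blood	M494	G	14294	16248	97.83	A	306	362	2.13
11	9196	G	A	mother	ATP6	N	Asp	Asn	child_blood	M494-C	G	10236	11242	99.95	A	0	3	0.014
11	3183	T	C	child	16S				mother_buccal	839	T	12953	24373	99.67	C	26	53	0.211
11	3183	T	C	child	16S				child_buccal	1189	T	12210	26317	96.49	C	412	937	3.37
11	3183	T	C	child	16S				mother_blood	M494	T	36453	46743	99.85	C	40	63	0.124
11	3183	T	C	child	16S				child_blood	M494-C	T	30655	39617	96.78	C	970	1333	3.17
11	15948	A	G	child	tRNA-Thr				mother_buccal	839	A	15680	15099	99.87	G	13	13	0.084
11	15948	A	G	child	tRNA-Thr				child_buccal	1189	A	21533	19721	95.35	G	1039	902	4.48
11	15948	A	G	child	tRNA-Thr				mother_blood	M494	A	24430	24443	99.95	G	7	7	0.029
11	15948	A	G	child	tRNA-Thr				child_blood	M494-C	A	30887	30673	96.64	G	1074	1041	3.32
12	11288	C	T	child	ND4	Y	Leu	Leu	mother_buccal	740	C	18404	14646	99.97	T	2	1	0.009
12	11288	C	T	child	ND4	Y	Leu	Leu	child_buccal	718	C	68908	55901	95.69	T	3140	2418	4.26
12	11288	C	T	child	ND4	Y	Leu	Leu	mother_blood	M211	C	38204	36874	99.95	T	8	17	0.033
12	11288	C	T	child	ND4	Y	Leu	Leu	child_blood	M211-C	C	46511	43582	96.58	T	1651	1523	3.4
13	596	T	C	mother	tRNA-Phe				mother_buccal	739	T	3088	856	84.7	C	552	155	15.18
13	596	T	C	mother	tRNA-Phe				child_buccal	725	T	9324	2728	99.37	C	3	13	0.132
13	596	T	C	mother	tRNA-Phe				mother_blood	M200	T	1745	1125	95.15	C	93	52	4.8
13	596	T	C	mother	tRNA-Phe				child_blood	M200-C	T	5520	3270	99.82	C	8	4	0.136
14	926	A	G	mother	12S				mother_buccal	605	A	7528	4119	96.48	G	275	147	3.49
14	926	A	G	mother	12S				child_buccal	619	A	23698	18664	99.95	G	7	5	0.028
14	926	A	G	mother	12S				mother_blood	M240	A	3882	3469	96.29	G	149	131	3.66
14	926	A	G	mother	12S				child_blood	M240-C	A	4476	4483	99.92	G	2	2	0.043
15	14573	A	G	mother	ND6	N	Val	Ala	mother_buccal	632	A	3406	2340	70.79	G	1390	966	29.02
15	14573	A	G	mother	ND6	N	Val	Ala	child_buccal	696	A	5484	4707	99.73	G	1	4	0.049
15	14573	A	G	mother	ND6	N	Val	Ala	mother_blood	M236	A	7546	6525	77.51	G	2240	1839	22.47
15	14573	A	G	mother	ND6	N	Val	Ala	child_blood	M236-C	A	8151	7438	99.95	G	3	1	0.026
15	214	A	G	child	CR				mother_buccal	632	A	886	2300	99.75	G	3	4	0.219
15	214	A	G	child	CR				child_buccal	696	A	1739	2434	91.43	G	156	230	8.45
15	214	A	G	child	CR				mother_blood	M236	A	3777	4526	99.99	G	0	1	0.012
15	214	A	G	child	CR				child_blood	M236-C	A	3426	4146	96.87	G	119	124	3.1
16	16240	A	G	child	CR				mother_buccal	531	A	1424	1744	99.75	G	3	2	0.157
16	16240	A	G	child	CR				child_buccal	572	A	24590	25415	90.81	G	2527	2455	9.04
16	16240	A	G	child	CR				mother_blood	M-188	A	16073	16853	99.88	G	4	9	0.039
16	16240	A	G	child	CR				child_blood	M188-C	A	13732	14444	94.28	G	823	855	5.61
17	9983	A	G	child	CO3	Y	Trp	Trp	mother_buccal	616	A	2944	7014	99.83	G	5	12	0.17
17	9983	A	G	child	CO3	Y	Trp	Trp	child_buccal	643	A	11623	20991	97.33	G	314	547	2.56
17	9983	A	G	child	CO3	Y	Trp	Trp	mother_blood	M252	A	11354	14962	99.83	G	18	22	0.152
17	9983	A	G	child	CO3	Y	Trp	Trp	child_blood	M252-C	A	17123	22272	97.91	G	346	468	2.02
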