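pair	slot	sample_code	np	ref	minor	major	minor_pct
1	mother_buccal	807	16183	A	G	A	7.32
1	child_buccal	803	16183	A	G	A	6.89
1	mother_blood	M490	16183	A	G	A	2.81
1	child_blood	M490-C	16183	A	G	A	2.46
2	mother_buccal	618	16189	T	C	T	7.74
2	child_buccal	606	16189	T	C	T	11.07
2	mother_blood	M249	16189	T	C	T	2.81
2	child_blood	M249-C	16189	T	C	T	9.92
3	mother_buccal	704	6152	T	C	T	7.23
3	child_buccal	630	6152	T	C	T	16.37
3	mother_blood	M234	6152	T	C	T	5.04
3	child_blood	M234-C	6152	T	C	T	16.48
4	mother_buccal	762	10873	T	C	T	2.53
4	child_buccal	702	10873	T	C	T	6.66
4	mother_blood	M210	10873	T	C	T	ND
4	child_blood	M210-C	10873	T	C	T	5.4
5	mother_buccal	729	1656	A	A	G	2.11
5	child_buccal	684	1656	A	A	G	2.52
5	mother_blood	M213	1656	A	A	G	2.77
5	child_blood	M213-C	1656	A	A	G	2.68
6	mother_buccal	1091	3243	A	G	A	30.72
6	child_buccal	1111	3243	A	A	G	33.1
6	mother_blood	M512	3243	A	G	A	13.13
6	child_blood	M512-C	3243	A	A	G	41.01
6	mother_buccal	1091	5539	A	A	G	41.94
6	child_buccal	1111	5539	A	G	A	24.54
6	mother_blood	M512	5539	A	A	G	23.13
6	child_blood	M512-C	5539	A	G	A	31.26
6	mother_buccal	1091	16192	C	C	T	19.23
6	child_buccal	1111	16192	C	C	T	14.1
6	mother_blood	M512	16192	C	C	T	22.78
6	child_blood	M512-C	16192	C	C	T	17.3
7	mother_buccal	1098	16093	T	C	T	11.53
7	child_buccal	1100	16093	T	T	C	3.45
7	mother_blood	M520	16093	T	C	T	9.12
7	child_blood	M520-C	16093	T	T	C	ND
8	mother_buccal	1267	2352	T	T	C	48.11
8	child_buccal	1160	2352	T	T	C	26.81
8	mother_blood	SC16	2352	T	T	C	47.93
8	child_blood	SC16-C	2352	T	T	C	26.84
9	mother_buccal	839	11635	C	T	C	8.34
9	child_buccal	1189	11635	C	T	C	17.93
9	mother_blood	M494	11635	C	T	C	7.23
9	child_blood	M494-C	11635	C	T	C	19.88
10	mother_buccal	632	15047	G	A	G	21.08
10	child_buccal	696	15047	G	A	G	26.67
10	mother_blood	M236	15047	G	A	G	19.47
10	child_blood	M236-C	15047	G	A	G	28.22
11	mother_buccal	531	5107	C	T	C	9.74
11	child_buccal	572	5107	C	T	C	13.07
11	mother_blood	M-188	5107	C	T	C	8.19
11	child_blood	M188-C	5107	C	T	C	10.05
12	mother_buccal	616	15262	T	C	T	8.36
12	child_buccal	643	15262	T	C	T	15.81
12	mother_blood	M252	15262	T	C	T	7.46
12	child_blood	M252-C	15262	T	C	T	15.49
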