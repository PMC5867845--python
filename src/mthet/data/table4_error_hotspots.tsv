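miscalled_base	adjacent_sequence	ref_nt	np	error_pct
A	AAA*TAC	C	2785	0.669
A	TCA*AAG	T	2445	0.722
A	ATA*AAAA	T	6415	0.732
A	AAA*AGT	C	2756	0.836
A	AGA*GAG	C	2718	0.875
A	AAG*AAC	G	2471	0.9
A	CAA*ACG	G	2716	0.92
A	GAA*ACC	G	2724	1.013
A	AAC*AAC	T	10304	1.018
A	AAAAA*AAAAAA	T	8496	1.079
A	AAC*AAAA	C	8523	1.095
A	CTA*AAA	G	10260	1.13
A	AAG*AAA	G	2449	1.223
A	CCA*AAAAA	T	8490	1.395
A	CTA*AAA	C	10296	1.421
A	AGT*AAA	T	1115	1.517
A	CAC*AAA	C	3477	1.668
A	TAA*ACA	C	2708	2.048
A	AAC*AAAA	G	8533	2.355
A	GGT*AAAAAAA	T	2456	2.457
A	CCA*AAAA	T	3464	2.784
A	CGG*AAA	C	2479	3.371
A	AAAAA*TTC	T	2806	3.634
A	CCCC*AAAA	T	3488	4.629
A	AAAAAAAG*AAAAGG	T	2465	4.787
C	AAC*CTA	A	1142	1.971
C	TCT*CAC	T	3473	1.996
C	CTC*CCA	A	14914	2.01
C	ATT*CCC	A	2412	2.051
C	TAG*CCT	G	8573	2.157
C	ATC*CCG	A	3523	2.214
C	TCC*CCA	A	297	2.261
C	AAC*CGG	T	2475	2.363
C	CCCC*CCCC	A	14813	2.532
C	TAA*CCT	A	1104	2.629
C	CCCCCCC*CCCCC	T	310	2.702
C	TAC*CCT	A	6355	2.84
C	TGA*CCC	G	10290	3.22
C	CAA*CCCCCCC	A	302	3.259
C	GAT*CCCC	A	1082	3.365
C	TCT*CCA	A	3505	3.387
C	CAA*CCC	A	8512	3.419
C	ATT*CCT	A	10239	3.531
C	CCC*CCC	A	6316	3.635
C	AAA*CTC	A	3468	4.003
C	TCC*CCC	A	5208	4.003
C	CCT*CCC	A	8577	4.318
C	AGA*CCCC	G	3483	4.614
C	ACA*CCC	A	3447	4.753
C	CAA*CCT	T	8567	4.799
C	TTC*CCA	A	3475	4.954
C	CCT*CCA	A	10283	5.115
C	AAA*CCC	A	3492	5.852
C	ATT*CCCCC	G	8557	5.99
C	AAC*CCC	A	5192	6.157
C	CTA*CCT	A	10306	6.723
C	TTTT*CCCC	A	10277	7.21
C	AAA*CCCCC	A	6419	10.035
C	ATC*CCC	A	3511	11.371
C	CTT*CCCC	A	2487	14.821
G	CAC*CCC	T	466	0.301
G	CAG*GCC	A	3243	0.301
G	AAC*GGC	T	5717	0.311
G	GAG*GTT	T	944	0.32
G	GGGG*AGC	A	16037	0.325
G	AAA*CCCCC	A	16183	0.326
G	CCC*CCC	A	16293	0.328
G	CAG*TTA	T	578	0.329
G	TGG*GAT	T	2010	0.329
G	AAC*CGG	T	2475	0.337
G	CGC*GAC	T	3456	0.347
G	TTA*CCC	C	10287	0.358
G	AGG*GTA	T	1335	0.376
G	AAG*GCC	A	5539	0.382
G	AGG*GGC	T	1349	0.406
G	CCG*ATA	T	7429	0.444
G	CGG*GCT	T	1180	0.487
G	GGG*ATA	C	2703	0.501
G	AAC*GCT	T	1129	0.577
G	AAC*GGG	T	1071	0.628
G	AAG*GCC	A	3482	0.672
G	AGG*CCT	T	2778	0.95
G	TGG*TTC	T	7480	1.069
G	AGG*TAT	T	7522	1.183
G	TGG*GCT	A	2734	2.458
T	ATC*CCC	A	16	0.345
T	CAA*CCCCCCC	A	302	0.343
T	GTC*CCCCCC	A	432	0.322
T	ACA*TTA	G	1113	0.32
T	GAT*AAAA	T	2352	0.834
T	AAG*TTA	G	2454	0.63
T	TTT*ATT	A	2740	1.058
T	TTT*TTA	A	2745	0.679
T	ATT*ATG	A	2748	0.57
T	TAT*CCC	A	4455	0.347
T	CTA*TAC	C	5107	0.36
T	TCT*CCT	A	5347	0.348
T	ATC*CCT	A	7649	0.346
T	TCT*TTC	G	8541	0.509
T	TCG*TTC	C	8546	0.579
T	TTC*TTC	A	8550	0.382
T	AGC*GGC	G	8856	0.41
T	ACC*CCT	A	9425	0.333
T	CAG*CAC	C	11635	0.377
T	CCCCCC*CTA	A	11873	0.354
T	ACC*CCC	A	12400	0.331
T	GCT*CCT	A	14988	0.37
T	ATC*CCT	A	15401	0.426
T	TCC*CCC	A	15408	0.579
T	CCC*CCC	A	16293	0.341
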