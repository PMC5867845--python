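name	category	start	end	strand	frame_start
CR	control_region	16024	576	H
tRNA-Phe	tRNA	577	647	H
12S	rRNA	648	1601	H
tRNA-Val	tRNA	1602	1670	H
16S	rRNA	1671	3229	H
tRNA-Leu(UUR)	tRNA	3230	3304	H
ND1	protein_coding	3307	4262	H	3307
tRNA-Ile	tRNA	4263	4331	H
tRNA-Gln	tRNA	4329	4400	L
tRNA-Met	tRNA	4402	4469	H
ND2	protein_coding	4470	5511	H	4470
tRNA-Trp	tRNA	5512	5579	H
tRNA-Ala	tRNA	5587	5655	L
tRNA-Asn	tRNA	5657	5729	L
tRNA-Cys	tRNA	5761	5826	L
tRNA-Tyr	tRNA	5826	5891	L
CO1	protein_coding	5904	7445	H	5904
tRNA-Ser(UCN)	tRNA	7446	7514	L
tRNA-Asp	tRNA	7518	7585	H
CO2	protein_coding	7586	8269	H	7586
tRNA-Lys	tRNA	8295	8364	H
ATP8	protein_coding	8366	8572	H	8366
ATP6	protein_coding	8527	9207	H	8527
CO3	protein_coding	9207	9990	H	9207
tRNA-Gly	tRNA	9991	10058	H
ND3	protein_coding	10059	10404	H	10059
tRNA-Arg	tRNA	10405	10469	H
ND4L	protein_coding	10470	10766	H	10470
ND4	protein_coding	10760	12137	H	10760
tRNA-His	tRNA	12138	12206	H
tRNA-Ser(AGY)	tRNA	12207	12265	H
tRNA-Leu(CUN)	tRNA	12266	12336	H
ND5	protein_coding	12337	14148	H	12337
ND6	protein_coding	14149	14673	L	14673
tRNA-Glu	tRNA	14674	14742	L
CYB	protein_coding	14747	15887	H	14747
tRNA-Thr	tRNA	15888	15953	H
tRNA-Pro	tRNA	15956	16023	L
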