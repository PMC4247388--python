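gene	transcript_id	logfc	p_raw	p_adj	b
Adamts13	ENSMUST00000102891	-3.84	5.55E-006	8.95E-004	4.06
Arap3	ENSMUST00000042944	-2.40	9.01E-007	1.96E-004	5.81
Atp6v1b2	ENSMUST00000006435	2.94	1.42E-008	1.34E-005	9.66
BC027231	ENSMUST00000048788	-3.12	6.29E-007	1.61E-004	6.15
Bgn	ENSMUST00000033741	-2.45	8.00E-006	1.13E-003	3.70
Card10	ENSMUST00000164826	-3.61	2.61E-007	8.67E-005	7.00
Cited2	ENSMUST00000038107	-3.08	1.14E-005	1.37E-003	3.37
Cxx1b	ENSMUST00000088778	-3.87	3.26E-007	9.67E-005	6.78
Cyp2r1	ENSMUST00000032908	3.42	5.80E-007	1.56E-004	6.21
Dtd1	ENSMUST00000028917	-2.16	6.96E-007	1.64E-004	6.06
Epg5	ENSMUST00000044622	-4.10	2.70E-006	5.26E-004	4.76
Epha2	ENSMUST00000006614	-2.76	5.78E-006	8.98E-004	4.03
Fam129b	ENSMUST00000028135	-2.97	3.10E-007	9.67E-005	6.83
Fam92a	ENSMUST00000108285	2.96	6.59E-007	1.62E-004	6.09
Fbln5	ENSMUST00000021603	-4.57	5.76E-008	4.65E-005	8.43
Grb14	ENSMUST00000028252	5.21	4.61E-009	5.20E-006	10.73
Ift122	ENSMUST00000112923	-3.02	6.41E-006	9.52E-004	3.93
Igj	ENSMUST00000087033	-3.30	9.15E-006	1.20E-003	3.59
Insig1	ENSMUST00000059155	3.04	8.94E-006	1.20E-003	3.63
Ints2	ENSMUST00000018212	-2.85	5.89E-006	8.98E-004	4.01
Iqsec1	ENSMUST00000189881	5.16	2.00E-007	7.52E-005	7.22
Lgals3	ENSMUST00000142734	-3.58	1.15E-007	6.48E-005	7.78
Lrrfip2	ENSMUST00000035078	2.61	2.52E-007	8.67E-005	6.99
Masp2	ENSMUST00000052060	3.46	2.63E-009	4.94E-006	11.32
Med28	ENSMUST00000156481	3.16	1.93E-006	3.89E-004	5.08
Nemf	ENSMUST00000021368	3.48	3.17E-006	5.77E-004	4.61
Ngef	ENSMUST00000068681	5.16	1.26E-007	6.48E-005	7.65
Nos3	ENSMUST00000030834	-3.58	7.94E-006	1.13E-003	3.72
Orc5	ENSMUST00000030872	2.69	1.92E-006	3.89E-004	5.09
Pdgfrb	ENSMUST00000115274	-4.44	3.62E-006	6.38E-004	4.48
Perp	ENSMUST00000019998	4.91	6.10E-010	3.44E-006	12.57
Pglyrp2	ENSMUST00000170392	6.23	1.25E-009	3.52E-006	11.93
Rasip1	ENSMUST00000057927	-4.69	9.75E-008	6.11E-005	7.94
Rnase4	ENSMUST00000022428	3.21	3.60E-007	1.01E-004	6.69
Rpa2	ENSMUST00000102561	-2.42	2.87E-006	5.41E-004	4.70
Rpusd4	ENSMUST00000034543	-4.13	1.84E-007	7.52E-005	7.33
Slc25a38	ENSMUST00000035106	2.90	8.36E-007	1.89E-004	5.87
Smad2	ENSMUST00000168423	2.12	1.58E-005	1.81E-003	3.09
Ssbp4	ENSMUST00000049908	-2.50	8.39E-006	1.15E-003	3.68
Tie1	ENSMUST00000047421	-3.79	8.04E-008	5.67E-005	8.12
Timp2	ENSMUST00000017610	-5.09	3.71E-009	5.20E-006	11.02
Top1	ENSMUST00000109468	2.18	1.07E-005	1.35E-003	3.45
Vac14	ENSMUST00000034190	-2.27	1.87E-007	7.52E-005	7.32
Wsb1	ENSMUST00000017821	-4.40	1.57E-007	7.40E-005	7.48
Zfp143	ENSMUST00000084727	-2.43	5.19E-006	8.62E-004	4.13
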