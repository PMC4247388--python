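gene	transcript_id	logfc	p_raw	p_adj	b
Adamts1	ENSMUST00000023610	-2.08	2.6E-07	1.0E-04	6.98
Ankrd6	ENSMUST00000035719	-3.37	2.5E-06	3.2E-04	4.84
Arhgef19	ENSMUST00000006618	-3.41	2.9E-07	1.0E-04	6.89
Arl2	ENSMUST00000025893	-2.36	1.2E-06	2.2E-04	5.52
Atp5g2	ENSMUST00000185641	-2.22	8.6E-07	1.8E-04	5.83
Cdh3	ENSMUST00000080797	-3.41	7.6E-06	6.6E-04	3.73
Cep170	ENSMUST00000057037	-2.71	1.5E-06	2.3E-04	5.36
Cpsf3l	ENSMUST00000030901	-2.44	3.3E-06	3.9E-04	4.52
Cxx1b	ENSMUST00000088778	-2.29	1.6E-06	2.3E-04	5.25
Dennd4b	ENSMUST00000098914	-2.68	2.3E-06	3.0E-04	4.92
E4f1	ENSMUST00000056032	-2.08	1.7E-05	1.1E-03	2.99
Egr1	ENSMUST00000064795	-4.04	2.2E-07	9.4E-05	7.16
Epb4.1l2	ENSMUST00000053748	-2.41	2.2E-08	2.0E-05	9.36
Fancg	ENSMUST00000030165	-3.22	1.0E-05	7.6E-04	3.51
Galnt11	ENSMUST00000045737	2.33	7.9E-06	6.6E-04	3.69
Gja4	ENSMUST00000053753	-3.17	7.3E-08	4.8E-05	8.21
Gltscr2	ENSMUST00000044158	-2.60	2.2E-08	2.0E-05	9.40
Hdac11	ENSMUST00000041736	-2.01	8.3E-07	1.8E-04	5.89
Heatr1	ENSMUST00000059270	2.60	1.2E-06	2.2E-04	5.47
Hecw2	ENSMUST00000120904	-2.62	7.8E-07	1.8E-04	5.94
Hoxa5	ENSMUST00000048794	-3.44	7.9E-06	6.6E-04	3.73
Igsf11	ENSMUST00000023478	4.09	9.2E-07	1.9E-04	5.72
Junb	ENSMUST00000064922	-3.44	1.5E-06	2.3E-04	5.29
Klf9	ENSMUST00000036884	2.26	9.3E-06	7.2E-04	3.60
Lig1	ENSMUST00000177588	-2.50	9.3E-06	7.2E-04	3.54
Lrfn4	ENSMUST00000113822	-2.78	5.0E-07	1.4E-04	6.37
Marc2	ENSMUST00000068725	5.01	2.6E-07	1.0E-04	6.90
Ncapd2	ENSMUST00000043848	-2.14	1.3E-08	1.5E-05	9.91
Ncs1	ENSMUST00000000199	-2.40	8.7E-07	1.8E-04	5.84
Nfya	ENSMUST00000046719	3.45	2.2E-07	9.4E-05	7.02
Nipsnap3b	ENSMUST00000015391	-2.47	5.0E-06	5.0E-04	4.18
Nle1	ENSMUST00000103213	-3.32	7.1E-10	2.6E-06	12.57
Nme6	ENSMUST00000035053	2.34	4.7E-07	1.4E-04	6.30
Nr4a1	ENSMUST00000023779	-5.09	1.5E-07	7.7E-05	7.53
Palld	ENSMUST00000121785	4.13	7.0E-09	1.3E-05	10.13
Pmf1	ENSMUST00000056370	-2.39	8.1E-06	6.7E-04	3.72
Pomk	ENSMUST00000061850	-2.21	1.0E-06	2.0E-04	5.72
Por	ENSMUST00000005651	2.49	4.8E-06	5.0E-04	4.18
Prelid1	ENSMUST00000021942	2.72	1.4E-07	7.7E-05	7.56
Prkcdbp	ENSMUST00000047040	-3.03	1.6E-06	2.3E-04	5.25
Psmg3	ENSMUST00000031531	-2.12	3.8E-06	4.3E-04	4.43
Rpa2	ENSMUST00000102561	-2.61	1.2E-08	1.5E-05	9.95
Rpl10	ENSMUST00000008826	-2.37	7.7E-07	1.8E-04	5.93
Rps17	ENSMUST00000080813	-2.34	1.1E-05	7.9E-04	3.33
Scg5	ENSMUST00000024005	-2.81	6.8E-07	1.7E-04	6.07
Sema4c	ENSMUST00000114991	-2.55	1.4E-07	7.7E-05	7.58
Sprtn	ENSMUST00000034467	-2.14	1.6E-06	2.3E-04	5.25
St7	ENSMUST00000081635	2.56	9.5E-06	7.3E-04	3.58
Syf2	ENSMUST00000030622	2.03	1.2E-05	8.6E-04	3.33
Tle2	ENSMUST00000146358	-2.60	1.6E-06	2.3E-04	5.25
Traf1	ENSMUST00000172159	-3.11	1.2E-06	2.2E-04	5.56
Usp9x	ENSMUST00000089302	5.60	5.1E-11	3.7E-07	14.39
Zdhhc1	ENSMUST00000044286	-2.16	3.7E-09	8.9E-06	11.09
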