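gene	transcript_id	logfc	p_raw	p_adj	b
Asl	ENSMUST00000161094	-4.40	1.43E-005	1.50E-002	3.19
Brk1	ENSMUST00000035725	-2.85	5.69E-006	7.93E-003	3.96
Eif3l	ENSMUST00000040518	-2.46	2.28E-006	4.77E-003	4.95
Htatip2	ENSMUST00000085272	-6.00	1.40E-007	5.87E-004	6.99
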