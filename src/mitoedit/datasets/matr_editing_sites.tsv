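genome_pos	tpos	aa_pos	ref_codon	edited_codon	aa_change	mean_N	sd_N	letter_N	mean_SR	sd_SR	letter_SR	mean_UR	sd_UR	letter_UR	diff_N_UR	diff_N_SR	diff_SR_UR	in_arabidopsis	arabidopsis_degree	in_soybean_prior
340005	32	11	TCC	TTC	S>F	88	3	a	72	3	b	67	4	b	21	16	5	No		Yes
339890	147	49	TTC	TTT	No (F)	26	1	a	12	2	b	13	4	b	13	14	-1	No		No
339844	193	65	CCA	TCA	P>S	92	3	a	79	2	b	77	3	b	15	13	2	No		Yes
339801	236	79	TCC	TTT	S>F	93	2	a	81	2	b	69	2	c	24	12	12	No		Yes
339711	326	109	CCA	CTA	P>L	75	4	a	69	1	b	74	2	a	0	6	-6	Yes	87	Yes
339633	404	135	TCG	TTG	S>L	84	0	a	48	3	b	63	2	c	20	35	-15	Yes	90	No
339126	911	304	GCC	GTC	A>V	17	2	a	13	0	b	19	5	ab	-2	4	-6	No		No
338976	1061	354	CCC	CTC	P>	77	2	a	47	6	b	61	2	c	15	30	-15	No		Yes
338495	1542	514	CCC	CCT	No (P)	42	1	a	22	2	b	20	4	b	22	20	2	Yes	43	No
338361	1676	559	TCT	TTT	S>F	91	1	a	79	2	b	87	1	c	4	13	-9	Yes	88	Yes
338340	1697	566	CCT	CTT	P>L	91	1	a	68	2	b	84	1	c	7	23	-16	Yes	84	Yes
338320	1717	573	CGC	TGT	R>C	80	2	a	55	2	b	69	2	c	11	25	-14	Yes	83	Yes
338306	1731	577	TAC	TAT	No (Y)	97	1	a	93	1	b	95	0	c	2	4	-2	No		No
338284	1753	585	CAC	TAC	H>Y	93	0	a	78	2	b	88	1	c	5	15	-10	Yes	79	Yes
338214	1823	608	CCC	CTC	P>L	83	1	a	72	1	b	71	1	b	12	11	2	No		Yes
338196	1841	614	TCA	TTA	S>L	97	1	a	91	1	b	96	1	a	1	7	-5	Yes	93	Yes
338186	1851	617	GTC	GTT	No (V)	42	2	a	33	1	b	39	2	a	3	9	-6	No		No
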