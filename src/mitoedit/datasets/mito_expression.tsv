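gene_id	gene	description	fpkm_UR	fpkm_SR	fpkm_N	ratio_N_UR	p_N_UR	bold_N_UR	ratio_N_SR	p_N_SR	bold_N_SR	ratio_SR_UR	p_SR_UR	bold_SR_UR
GlmaxMp01	ccmC	cytochrome c biogenesis C	15863	20620	10842	0.68	0.000	False	0.53	0.000	True	1.30	0.001	False
GlmaxMp51	ccmFn	cytochrome c biogenesis FN	4048	2982	1586	0.39	0.000	True	0.53	0.000	True	0.74	0.006	False
GlmaxMp04	cox3	cytochrome c oxidase subunit III	31643	31486	60520	1.91	0.000	True	1.92	0.000	True	1.00	0.943	False
GlmaxMp20-2	nad1	NADH dehydrogenase subunit 1	12430	21952	27133	2.18	0.000	True	1.24	0.002	False	1.77	0.000	True
GlmaxMp31-1	nad2	NADH dehydrogenase subunit 2	12565	19324	16626	1.32	0.048	False	0.86	0.001	False	1.54	0.009	True
GlmaxMp32	nad4L-1	NADH dehydrogenase subunit 4L	30659	51843	39578	1.29	0.257	False	0.76	0.007	False	1.69	0.035	True
GlmaxMp46	nad4L-2	NADH dehydrogenase subunit 4L	29685	47502	36863	1.24	0.353	False	0.78	0.009	False	1.60	0.057	True
GlmaxMp05-1	nad5	NADH dehydrogenase subunit 5	17739	26994	25170	1.42	0.025	False	0.93	0.036	False	1.52	0.014	True
GlmaxMp05-2	nad5	NADH dehydrogenase subunit 5	26303	42023	55654	2.12	0.000	True	1.32	0.003	False	1.60	0.004	True
GlmaxMp07	rpl5	ribosomal protein subunit L5	15181	19217	10240	0.67	0.145	False	0.53	0.000	True	1.27	0.213	False
GlmaxMp53	rps1	ribosomal protein S1	9695	21173	17874	1.84	0.013	True	0.84	0.005	False	2.18	0.004	True
GlmaxMp16	rps12	ribosomal protein S12	10421	11110	19813	1.90	0.001	True	1.78	0.000	True	1.07	0.572	False
GlmaxMp08	rps14	ribosomal protein subunit S14	24486	25459	14704	0.60	0.077	False	0.58	0.000	True	1.04	0.826	False
GlmaxMp52	rps4	ribosomal protein S4	6737	15174	16296	2.42	0.004	True	1.07	0.012	False	2.25	0.006	True
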