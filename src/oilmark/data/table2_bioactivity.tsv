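sample	oil	teac_mean	teac_sd	teac_letters	tpc_mean	tpc_sd	tpc_letters	tcc_mean	tcc_sd	tcc_letters
S_a	sunflower	252.22	3.65	bcd	4.33	0.13	hi	285.85	3.47	jk
S_b	sunflower	249.78	5.30	cde	4.24	0.07	hi	314.43	2.59	ijk
S_c	sunflower	222.44	0.66	de	12.6	0.09	gh	247.97	5.23	k
S_d	sunflower	282.38	12.28	bcd	nd	nd	i	256.55	5.86	k
Ses_a	sesame	181.65	2.30	fgh	94.57	4.44	b	340.49	6.46	ij
Ses_b	sesame	148.10	6.06	h	84.03	4.19	c	286.36	7.44	jk
Ses_c	sesame	219.54	7.64	def	99.05	3.35	ab	363.29	5.89	i
Ses_d	sesame	165.36	5.41	gh	103.79	3.67	a	259.29	6.22	k
R_a	rapeseed	240.56	1.82	cde	20.43	0.57	g	3196.71	64.5	a
R_b	rapeseed	202.85	4.12	efg	61.11	0.76	d	1253.74	17.82	e
R_c	rapeseed	291.16	1.98	ab	48.20	2.26	e	3038.1	56.81	b
R_d	rapeseed	244.85	11.56	cde	30.1	1.06	f	1638.73	17.69	c
F_a	flax	297.22	2.32	a	31.29	1.20	f	1501.91	12.02	d
F_b	flax	284.64	3.90	abc	18.10	0.42	g	1148.35	14.92	f
F_c	flax	269.30	11.19	bcd	44.76	1.40	e	927.03	11.54	h
F_d	flax	245.67	7.59	cde	45.13	2.05	e	1034.51	9.31	g
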