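rsid	flank5	wt	mut	flank3	note	kd_wt_expected	kd_mut_expected	direction_expected	z_expected	alpha_expected
rs11568827	aggggccagg	g	-	tataaaaagg	GH1	1.5	1.4	insignificant	1	-
rs796237787	gaaggggcca	g	-	ggtataaaaa	GH1	1.5	1.4	insignificant	1	-
rs768454929	agggtataaa	a	c	agggcccaca	GH1	1.5	2.6	down	7	1e-06
rs761695685	gccagggtat	a	g	aaaagggccc	GH1	1.5	5.8	down	19	1e-06
rs774326004	ccagggtata	a	t	aaagggccca	GH1	1.5	0.9	up	7	1e-06
rs777003420	aaggggccag	g	t	gtataaaaag	GH1	1.5	1.3	up	3	0.05
rs1143627	ttttgaaagc	c	t	ataaaaacag	IL1B	5	2	up	15	1e-06
rs549858786	tgaaagccat	a	t	aaaacagcga	IL1B	5	6	down	8	1e-06
rs7277748	ggtctggcct	a	g	taaagtagtc	SOD1	7	2	up	17	1e-06
rs16887226	cagccttcag	c	t	gggggacatt	StAR	10	10	insignificant	1	-
rs544850971	tcagcggggg	a	g	catttaagac	StAR	10	12	down	5	1e-06
NOS2_-51T>C	gtataaatac	t	c	tcttggctgc	NOS2	2	1	up	3	1e-02
rs35036378	cctctcggtc	t	g	ttaaaaggaa	ESR2	6	8	down	5	1e-03
rs766797386	ttaaaaggaa	g	t	aaggggctta	ESR2	6	7	down	3	1e-02
rs397509430	gggctgggca	t	-	atacaacagt	HBB	5	29	down	34	1e-06
rs33980857	gggctgggca	t	a,g,c	atacaacagt	HBB	5	21	down	27	1e-06
rs34598529	ggctgggcat	a	g	aaagtcaggg	HBB	5	18	down	24	1e-06
rs33931746	gctgggcata	a	g,c	aagtcagggc	HBB	5	11	down	14	1e-06
rs33981098	agggctgggc	a	g,c	taaaagtcag	HBB	5	9	down	10	1e-06
rs34500389	cagggctggg	c	a,t,g	ataaaagtca	HBB	5	6	down	3	1e-02
rs35518301	caggaccagc	a	g	taaaaggcag	HBD	4	8	down	11	1e-06
rs63750953	ctgggcataa	aa	-	gtcagggcag	HBB	5	8	down	9	1e-06
rs281864525	tgggcataaa	a	c	gtcagggcag	HBB	5	7	down	7	1e-06
rs34166473	aggaccagca	t	c	aaaaggcagg	HBD	4	8	down	18	1e-06
rs10895068	gggagataaa	g	a	gagccgcgtg	PGR	10	6	up	8	1e-06
rs201381696	tcgggccgct	a	g	taagaggggc	LEP	4	12	down	17	1e-06
rs200487063	tgatcgggcc	g	a	ctataagagg	LEP	4	2	up	6	1e-06
rs34104384	ccgctataag	a	t	ggggcgggca	LEP	4	3	up	4	1e-02
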