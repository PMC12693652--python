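isoform	accession	gene	T01	T02	T03	T04	T05	T06	T07	T08	T09	T10	T11	T12	T13	T14	T15	T16	T17	T18
PMCA1a	NP_001001323	ATP2B1	tgg	ttt	aga	ggt	ctg	aac	aga	atc	caa	aca	cag	atg	gat	gta	gtg	aat	gct	ttc
PMCA1b	NP_001353449.1	ATP2B1	tgg	ttt	aga	ggt	ctg	aac	aga	atc	caa	aca	cag	att	cga	gtg	gtg	aat	gca	ttt
PMCA4a	NP_001001396.1	ATP2B4	tgg	ttc	cgg	ggc	ctg	aac	cgt	atc	cag	act	cag	atc	gac	gta	att	aac	aca	ttc
PMCA4c	NP_001352712.1	ATP2B4	tgg	ttc	cgg	ggc	ctg	aac	cgt	atc	cag	act	cag	atc	gac	gta	att	aac	aca	ttc
PMCA2c	NP_001317540.1	ATP2B2	tgg	ttc	cga	ggc	ctg	aat	cgg	atc	cag	aca	cag	att	gaa	gtc	gtc	aat	act	ttc
PMCA2d	NP_001350791.1	ATP2B2	tgg	ttc	cga	ggc	ctg	aat	cgg	atc	cag	aca	cag	att	gaa	gta	gtc	aat	act	ttc
PMCA3a	NP_001375289.1	ATP2B3	tgg	ttc	cgg	ggc	ctg	aac	cgg	att	cag	acg	cag	atg	gag	gta	gtg	agt	acc	ttc
PMCA4b	NP_001675.3	ATP2B4	tgg	ttc	cgg	ggc	ctg	aac	cgt	atc	cag	act	cag	atc	aaa	gtg	gtc	aaa	gcg	ttc
PMCA2a	NP_001001331.1	ATP2B2	tgg	ttc	cga	ggc	ctg	aat	cgg	atc	cag	aca	cag	atc	cgc	gtc	gtg	aag	gcg	ttc
PMCA2b	NP_001340493.1	ATP2B2	tgg	ttc	cga	ggc	ctg	aat	cgg	atc	cag	aca	cag	atc	cgc	gtc	gtg	aag	gcg	ttc
PMCA3b	NP_001001344.1	ATP2B3	tgg	ttc	cgg	ggc	ctg	aac	cgg	att	cag	acg	cag	atc	cgg	gtg	gtg	aaa	gcg	ttc
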