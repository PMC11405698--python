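prey_id	cterm	annotation	search_method	e_value	query_cover	pct_id	species	accession	colonies
evg93589	QNRLGFAKAV	Cathepsin D	SmartBlast	1.0E-140	95.0%	53.4%	D. melanogaster	NP_001334713.1	4
TRINITY_DN22496_c0_g1_i1	FVEKSRCTLV	G protein Gamma 7	SmartBlast	1.0E-17	100.0%	50.0%	D. rerio	NP_001002397.1	2
evg19742	NSILSLPTTV	H/ACA ribonucleoprotein complex subunit 2	SmartBlast	4.0E-48	71.0%	48.7%	M. musculus	NP_080907.1	1
evg1173499	IHIYECPSNV	SKI8 subunit of superkiller complex protein	SmartBlast	3.0E-156	97.0%	65.8%	D. rerio	NP_957147.1	1
evg485730	REQDKRGNLV	4-hydroxyphenylpyruvate dioxygenase	SmartBlast	0.0E+00	98.0%	70.7%	D. rerio	XP_005171786.1	1
evg1106341	SGGPTIEEVD	Heat shock cognate 71 kDa protein	SmartBlast	0.0E+00	93.0%	88.4%	H. sapiens	NP_006588.1	1
evg1508575	GKSLRTVLNF	Alcohol dehydrogenase class-3	SmartBlast	9.0E+00	94.0%	74.3%	D. rerio	NP_571924.2	1
evg264334	RTERPRPRAY	40S ribosomal protein S2	SmartBlast	1.0E-136	84.0%	79.9%	M. musculus	NP_032529.2	1
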