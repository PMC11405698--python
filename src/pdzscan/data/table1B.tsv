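prey_id	cterm	annotation	search_method	e_value	query_cover	pct_id	species	accession	colonies
evg10473	LDINGFIIYI	3' UTR of: betaine-homocysteine S-methyltransferase 1	SmartBlast	7.0E-176	99.0%	65.9%	D. rerio	NP_001012498.1	17
evg929466	NKETIDAMEI	60S ribosomal protein L9	SmartBlast	1.0E-89	94.0%	67.0%	D. rerio	XP_005170964.1	1
evg1428490	LIESRNLAVI	Alt. ORF: Acid sphingomyelinase-like phosphodiesterase 3b	SmartBlast	3.0E-32	78.0%	26.2%	M. musculus	NP_598649.1	1
Not found	EVLSGSMFWV	Basic proline-rich protein-like	NCBI BLAST	3.0E-10	97.0%	42.4%	C. pelagica	XP_009995607.1	4
evg1363342	KLFHGWQAWV	Serine-protein kinase ATM	SmartBlast	0.0E+00	100.0%	34.5%	H. sapiens	XP_011541144.1	1
evg1036905	AQDGVIKVWV	Phosphoinositide 3-kinase regulatory subunit 4	SmartBlast	0.0E+00	99.0%	46.2%	D. rerio	XP_005158356.1	1
evg1095586	GHLTVLVAMV	Msx2-interacting protein	SmartBlast	3.0E-50	61.0%	46.2%	M. musculus	NP_001334164.1	1
evg1187940	ILNTTGAFNV	Multidrug and toxin extrusion protein 1	SmartBlast	5.0E-107	87.0%	36.7%	M. musculus	NP_080459.2	1
evg1106341	SGGPTIEEVD	Heat shock cognate 71 kDa protein	SmartBlast	0.0E+00	93.0%	88.4%	H. sapiens	NP_006588.1	1
evg108179	PSEISVTLRR	Carboxypeptidase D	SmartBlast	7.0E-138	97.0%	52.6%	H. sapiens	NP_001186704.1	1
evg1107053	LIKIDRKEEL	Peptidyl-prolyl cis-trans isomerase FKBP2	SmartBlast	1.0E-58	95.0%	64.0%	M. musculus	NP_001159840.1	1
evg1256402	MCIEINSRLL	Acetyl-CoA acetyltransferase	SmartBlast	9.0E-177	98.0%	59.3%	D. rerio	NP_571445.2	1
evg1382077	STKLEICSNS	lysine-specific demethylase 5A	SmartBlast	0.0E+00	82.0%	37.3%	H. sapiens	NP_001036068.1	1
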