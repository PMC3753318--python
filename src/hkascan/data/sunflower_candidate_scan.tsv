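role	locus	product	theta_wild	theta_landrace	theta_improved	p_wild	p_landrace	p_improved
neutral	c0025	Aleurain-like protease	0.0239	0.0150	0.0138	0.1937	0.2979	0.1760
neutral	c1111	Protein kinase family protein	0.0094	0.0006	0.0019	0.2125	0.6362	0.9305
neutral	c1351	Chlorophyll binding protein	0.0138	0.0180	0.0111	0.7964	0.7016	0.3830
neutral	c2016	DNAJ heat shock N-terminal domain-containing	0.0301	0.0189	0.0162	0.7361	0.8933	0.3601
neutral	c2307	Glyceraldehyde-3-phosphate dehydrogenase	0.0050	0.0055	0.0062	0.8146	0.7105	0.7910
neutral	c5369	S-adenosylmethionine synthetase	0.0111	0.0097	0.0052	0.8648	0.8339	0.7842
neutral	c5456	Vacuolar H+-ATPase subunit A	0.0185	0.0101	0.0054	0.2398	0.3041	0.8800
domestication-candidate	c1357	Pentatricopeptide repeat-containing protein	0.0107	0.0056	0.0056	0.6688	0.3820	0.2101
domestication-candidate	c1533	Microtubule-associated protein	0.0216	0.0096	0.0004	0.5902	0.9072	0.0151
domestication-candidate	c1649	Putative protein	0.0093	0.0087	0.0000	0.9578	0.9188	0.0029
domestication-candidate	c1666	Putative Ser/Thr protein kinase	0.0134	0.0139	0.0000	0.1076	0.0823	0.0452
domestication-candidate	c2873	11S globulin precursor	0.0047	0.0025	0.0000	0.8921	0.5324	0.1425
domestication-candidate	c2963	BEL1-related homeotic protein	0.0127	0.0018	0.0000	0.8280	0.1798	0.0007
domestication-candidate	c3115	Nicotinate phosphoribosyltransferase-like protein	0.0027	0.0000	0.0000	0.1256	0.9774	0.9065
domestication-candidate	c5898	Unknown protein	0.0162	0.0015	0.0008	0.7698	0.0744	0.0269
domestication-candidate	c4973	Chorismate synthase	0.0084	0.0000	0.0000	0.9106	0.0053	0.0062
domestication-candidate	G13K16	No significant similarity	0.0095	0.0033	0.0026	0.8837	0.2176	0.1488
domestication-candidate	H4B03	Kinesin-related protein (MKRP2)	0.0132	0.0030	0.0003	0.0570	0.2177	0.5660
domestication-candidate	M23M12	CONSTANS 3	0.0138	0.0052	0.0016	0.2596	0.2188	0.9425
domestication-candidate	N21O05	Thiol protease	0.0029	0.0000	0.0000	0.1685	0.0053	0.0050
improvement-candidate	c1144	Calmodulin-binding protein	0.0024	0.0023	0.0000	0.7282	0.5471	0.0093
improvement-candidate	c1236	NSL1 (NECROTIC SPOTTED LESIONS1)	0.0119	0.0068	0.0000	0.5399	0.5683	0.0051
improvement-candidate	c1258	11S globulin precursor	0.0107	0.0066	0.0000	0.9099	0.4632	0.0000
improvement-candidate	c1406	Protein kinase-like protein	0.0219	0.0194	0.0000	0.2071	0.1630	0.0050
improvement-candidate	c1700	Mitochondrial dicarboxylate carrier	0.0213	0.0136	0.0084	0.8200	0.9343	0.5555
improvement-candidate	c1774	No significant similarity	0.0106	0.0109	0.0033	0.9305	0.8681	0.3536
improvement-candidate	c0019	Unknown protein	0.0250	0.0183	0.0000	0.1993	0.1024	0.0036
improvement-candidate	c1921	Dof27	0.0154	0.0088	0.0010	0.9483	0.6381	0.0104
improvement-candidate	c2150	NADP-specific glutatamate dehydrogenase	0.0321	0.0076	0.0000	0.3002	0.5340	0.0450
improvement-candidate	c2588	ATIDD11 (INDETERMINATE-DOMAIN11)	0.0053	0.0087	0.0000	0.3958	0.8769	0.0017
improvement-candidate	c3070	Gly-rich RNA binding protein	0.0088	0.0067	0.0077	0.9702	0.7709	0.7452
improvement-candidate	c5666	Peroxidase	0.0237	0.0057	0.0000	0.3859	0.4254	0.0192
improvement-candidate	J22O06	Unknown protein	0.0264	0.0031	0.0000	0.3104	0.3827	0.0010
improvement-candidate	L2K11	SDL-1 protein	0.0038	0.0040	0.0024	0.0879	0.0457	0.1359
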