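specimen_id	locus_label	coverage	mutant_count	homopolymer
05	EGFR_ex19_E746_R748del_A750	1315	145	0
27	EGFR_ex19_E746_A750del	854	94	0
11	KRAS_ex2_G12A	1358	285	0
10b	EGFR_ex20_T790M	909	182	0
31	EGFR_ex19_E746_A750del	1081	65	0
13a	EGFR_ex19_L747_A750del_T751P	658	53	0
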