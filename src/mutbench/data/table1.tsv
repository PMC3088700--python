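case_id	specimen_label	histotype	sex	age	tissue_type	specimen_type	tumor_content_pct	allele_pct	tki_response	call_dideoxy	call_pyro	call_parallel	gene	mutation_label	sensitizing
01	none	AD	M	38	FF	wedge Bx	80	N/A	SD	WT	WT	WT	none	no mutation	false
14	none	SQ	M	67	FFPE	transbronchial Bx	95	N/A	SD	WT	WT	WT	none	no mutation	false
21	none	SQ	M	39	FFPE	Bx of chest wall	90	N/A	PD	WT	WT	WT	none	no mutation	false
26	none	AD	M	60	H&E	pleural effusion	5	N/A	PD	WT	WT	WT	none	no mutation	false
28	none	AD	F	69	FF	lung surgery	70	N/A	N/A	WT	WT	WT	none	no mutation	false
33	none	AD	M	61	FFPE	transbronchial Bx	80	N/A	N/A	WT	WT	WT	none	no mutation	false
34	none	AD	M	44	FFPE	lung surgery	80	N/A	N/A	WT	WT	WT	none	no mutation	false
02	none	AD	F	69	FFPE	CT-guided lung Bx	50	54	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1a)	true
03	none	AD	M	58	FFPE	cerebral surgery	80	30	PR	MUT	MUT	MUT	EGFR	EGFR exon 21 L858R	true
04	none	SQ	M	58	FFPE	transbronchial Bx	80	58	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_T751del, S752V	true
05	none	AD	M	76	FFPE	mediastinoscopy	50	11	PR	WT	MUT	MUT	EGFR	EGFR exon 19 E746_R748del,A750P	true
06	a	AD	M	40	FF	cervical LN Bx	70	36	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1b)	true
06	b	AD	M	40	CSF	lumbar puncture	N/A	68	RL	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1b)	true
08	none	AD	F	52	FFPE	supraclavicular LN Bx	80	49	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1b)	true
10	a	AD	F	63	FF	Liver Bx	80	95	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 L747_S752del, P753S	true
10	b	AD	F	63	FF	Liver Bx	80	20	RL	WT	MUT	MUT	EGFR	EGFR exon 20 T790M	false
12	none	AD	F	80	FF	lung sugery	90	52	PR	MUT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1a)	true
13	a	AD	M	62	H&E	pleural effusion	5	8	PR	WT	WT	MUT	EGFR	EGFR exon 19 L747_A750del, T751P	true
13	b	AD	M	62	FF	pleural effusion	70	74	RL	MUT	MUT	MUT	EGFR	EGFR exon 19 L747_A750del, T751P	true
27	none	AD	F	71	FF	CT-guided lung Bx	40	11	PR	WT	MUT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1a)	true
31	none	AD	F	66	FF	transbronchial Bx	60	6	PR	WT	WT	MUT	EGFR	EGFR exon 19 E746_A750del (Del-1b)	true
11	none	AD	M	55	FFPE	lung surgery	50	21	N/A	WT	MUT	MUT	KRAS	KRAS exon 2 G12A	false
19	none	AD	F	52	FFPE	lung surgery	50	36	SD	MUT	MUT	MUT	KRAS	KRAS exon 2 A11V; G12V	false
24	none	AD	M	69	FFPE	lung surgery	95	40	PD	MUT	MUT	MUT	KRAS	KRAS exon 2 G13C	false
30	none	AD	F	61	FFPE	lung surgery	35	29	PD	MUT	MUT	MUT	KRAS	KRAS exon 2 G12V	false
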