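group_id	stage	function	n_groups	gtr_rpkm	gtr_fc	ppl_rpkm	ppl_fc
MCL_5471	early	Hypothetical membrane protein	1	427.2	75.9	282.0	12.5
MCL_7627	early	SAM-dependent methyltransferase	1	958.5	57.4	44.3	9.2
MCL_3182	early	Membrane integrating ferric reductase	1	169.1	16.3	100.3	12.2
MCL_187	early	bZIP transcription factor	1	125.2	14.9	95.6	5.9
MCL_7588	early	Ribonuclease h-related	1	33.3	11.3	15.0	4.3
MCL_562	early	Zn(2)-C6 fungal transcription factor	1	74.3	9.4	60.5	28.3
MCL_1312	early	Hypothetical membrane protein	1	2182.6	8.6	233.5	4.9
MCL_4304	early	Receptor of activated protein kinase C	1	554.0	5.7	650.6	5.0
MCL_5286	early	SRP-dependent cotranslational protein	1	264.3	5.4	750.2	10.2
MCL_7002	early	Hypothetical membrane protein SignalP-TM	1	266.8	5.2	39.4	10.1
MCL_5385	early	Hyaluronan/mRNA-binding protein	1	677.0	5.1	357.2	4.8
RIBOSOMAL_COMBINED	early	Ribosomal structure	19	18084.9	4.9	16973.8	4.8
MCL_47	early	NmrA-like protein	1	26.2	4.9	60.2	10.2
MCL_1200	early	bZIP transcription factor	1	47.8	4.3	19.9	5.7
MCL_2183	early	Heme-thiolate peroxidase/peroxygenase	1	90.1	4.3	25.8	4.1
MCL_384	early	Hypothetical protein	1	186.1	4.1	233.3	4.2
MCL_7542	late	GH5, endo-beta-1,4-glucanase, SignalP-noTM	1	10613.2	24.1	12208.0	10.7
MCL_2441	late	GH3, beta-glucosidase, SignalP-noTM	1	3309.1	21.6	2982.9	5.0
MCL_2166	late	NAD(P)-binding oxidoreductase	1	765.7	8.6	963.4	5.3
MCL_4879	late	Aldo keto reductase	1	1298.5	7.9	945.9	5.6
MCL_2248	late	GH3, beta-glucosidase	1	487.1	7.7	639.3	6.5
MCL_5876	late	Uncharacterized UPF0261	1	37.2	6.9	138.8	9.2
MCL_6280	late	Uncharacterized UPF0303	1	678.8	6.9	1871.6	8.7
MCL_2280	late	Thioredoxin	1	1585.8	5.8	3622.7	5.9
MCL_7782	late	K(+) channel subunit/aldo keto reductase	1	4302.2	5.5	1197.9	10.6
MCL_3957	late	Malate synthase, glyoxysomal	1	1490.2	5.4	1028.4	5.1
MCL_3499	late	NADP-dependent 3-OH acid dehydrogenase	1	1014.0	5.0	1607.1	6.7
MCL_7264	late	Carboxyl esterase, SignalP-noTM	1	617.2	4.8	1459.4	8.0
MCL_6643	late	Sugar transporter	1	423.6	4.7	1065.4	4.1
MCL_1455	late	Malic enzyme	1	235.3	4.4	181.9	4.4
MCL_5447	late	Peptidyl-prolyl cis-trans isomerase	1	3444.1	4.3	4415.2	9.0
MCL_2204	late	Aldo keto reductase	1	2030.3	4.3	1376.7	7.9
MCL_3421	late	Aldo keto reductase	1	1140.9	4.1	538.6	5.1
MCL_2530	late	Glyoxalase/peptidase	1	130.7	4.0	599.1	4.5
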