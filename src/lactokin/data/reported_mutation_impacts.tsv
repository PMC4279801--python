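transcript_id	cluster	annotation	lineage_group	mutation_type	region	section
1751	1	Putative FAD monooxygenase	RUT C30	SNV	Promoter	NG14_RUTC30_lineage
54511	5	Putative POZ domain protein	RUT C30	SNV	Promoter	NG14_RUTC30_lineage
56077	5	Putative transcription factor	RUT C30	SNV	Promoter	NG14_RUTC30_lineage
77513	5	Putative fungal C6 transcription factor	RUT C30	SNV	Exon	NG14_RUTC30_lineage
121087	Not clustered	Putative 4Fe-4S ferredoxin domain protein	NG 14 & RUT C30	SNV	Promoter	NG14_RUTC30_lineage
54736	1	Putative ATP-dependent RNA helicase DED1	KDG-12 PC-3-7	SNV	Promoter	other_lineages
58427	1	Putative ATP-dependent RNA helicase DBP2	PC-3-7	SNV	Exon	other_lineages
71380	1	Putative 3-hydroxy-3-methylglutaryl-coenzyme A reductase	PC-3-7	SNV	Exon	other_lineages
78836	1	Putative mitochondrial phosphate carrier	PC-3-7	SNV	Exon	other_lineages
82512	1	Putative 26S proteasome transcription factor RPN4	PC-3-7	SNV	Promoter	other_lineages
122036	1	Putative 40S ribosomal protein S2 RPS2	QM9414 KDG-12 PC-3-7	InDel & SNV	Promoter & Terminator	other_lineages
63882	4	Putative mitochondrial 3-hydroxyisobutyryl-CoA hydrolase	PC-3-7	SNV	Terminator	other_lineages
124031	4	Putative 20S proteasome alpha 3 subunit PRE9	PC-3-7	SNV	Promoter	other_lineages
6108	5	Putative SAM binding domain protein	QM9414 KDG-12 PC-3-7	InDel	Intron	other_lineages
112390	5	Putative WD40 repeat domain protein	QM9414 KDG-12 PC-3-7	InDel	Terminator	other_lineages
120688	5	Putative protein of unknown function	QM9414 KDG-12 PC-3-7	InDel	Exon	other_lineages
110853	6	Putative glutathione S-transferase	PC-3-7	SNV	Terminator	other_lineages
77481	8	Putative D-xylulose 5-phosphate/D-fructose 6-phosphate phosphoketolase	PC-3-7	SNV	Exon	other_lineages
120749	8	Glycoside hydrolase family 1 BGL2	KDG-12 PC-3-7	SNV	Exon	other_lineages
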