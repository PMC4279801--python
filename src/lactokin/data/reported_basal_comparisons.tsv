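transcript_id	cluster	annotation	log2_ratio_rutc30_vs_ng14	average_reads
59272	1	Putative MFS transporter	-4.78	17462
82032	1	Putative protein of unknown function	4.46	32445
121491	1	Putative glycosyltransferase family 4	4.21	38826
61374	3	Putative MFS transporter	-5.99	7537
74156	3	Putative secreted pepsin PROA	-4.92	715
23717	4	Putative 2-keto-3-deoxy-L-galactonate aldolase	-4.86	7427
76155	4	Putative acid phosphatase	-4.85	23883
122582	4	Putative mitochondrial dihydrodipicolinate synthase	-4.38	8170
69115	7	Putative dienelactone hydrolase	-5.11	27147
69944	8	Putative glycoside hydrolase family 31	7.01	1685
73643	8	Glycoside hydrolase family 61 EGL4/CEL61A	4.34	4641
121127	8	Glycoside hydrolase family 3 BXL1	5.65	6623
123967	8	Hydrophobin HFB3	6.82	548
69276	9	Putative glycoside hydrolase family 30	4.15	556
72567	9	Glycoside hydrolase family 6 CBH2/CEL6A	4.64	10892
73638	9	Secreted cellulose induced protein CIP1	6.37	1326
76210	9	Glycoside hydrolase family 62 ABF2	7.65	653
120312	9	Glycoside hydrolase family 5 EGL2/CEL5A	7.41	2331
120961	9	Glycoside hydrolase family 61 CEL61B	4.36	434
121418	9	Carbohydrate esterase family AES1	6.76	1027
60945	Not clustered	Putative MFS transporter	-4.51	6194
79816	Not clustered	Putative transcriptional regulator GAL80	-9.65	90
123251	Not clustered	Putative NADH-quinone oxidoreductase	4.67	1687
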