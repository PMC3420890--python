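#section	name	length_nt	sample	unit	value	count
endogenous	Hprt1	1407	phRL-SV40	RPKM	9.78	776
endogenous	Hprt1	1407	pGL4-SV40	RPKM	9.23	595
endogenous	Hprt1	1407	pBS/pEGFP-C1	RPKM	12.72	820
endogenous	Tbp	1844	phRL-SV40	RPKM	3.71	386
endogenous	Tbp	1844	pGL4-SV40	RPKM	3.86	326
endogenous	Tbp	1844	pBS/pEGFP-C1	RPKM	4.44	375
endogenous	Alas1	2430	phRL-SV40	RPKM	2.30	315
endogenous	Alas1	2430	pGL4-SV40	RPKM	2.44	272
endogenous	Alas1	2430	pBS/pEGFP-C1	RPKM	2.74	305
endogenous	B2-microglobulin	1715	phRL-SV40	RPKM	9.04	874
endogenous	B2-microglobulin	1715	pGL4-SV40	RPKM	7.35	578
endogenous	B2-microglobulin	1715	pBS/pEGFP-C1	RPKM	10.37	815
endogenous	B-actin	1917	phRL-SV40	RPKM	21.75	2350
endogenous	B-actin	1917	pGL4-SV40	RPKM	23.09	2029
endogenous	B-actin	1917	pBS/pEGFP-C1	RPKM	17.55	1542
endogenous	G-tubulin	1949	phRL-SV40	RPKM	2.68	294
endogenous	G-tubulin	1949	pGL4-SV40	RPKM	3.27	292
endogenous	G-tubulin	1949	pBS/pEGFP-C1	RPKM	2.98	266
endogenous	Gapdh	1875	phRL-SV40	RPKM	199.19	21055
endogenous	Gapdh	1875	pGL4-SV40	RPKM	201.25	17295
endogenous	Gapdh	1875	pBS/pEGFP-C1	RPKM	186.88	16060
plasmid	EGFP	798	pBS/pEGFP-C1	RPKM	5517.95	201821
plasmid	Renilla luciferase	936	phRL-SV40	RPKM	351.44	18544
plasmid	Firefly luciferase	1653	pGL4-SV40	RPKM	137.60	10425
plasmid	Ampicillin CDS	861	phRL-SV40	RPKM	203.04	9855
plasmid	Ampicillin CDS	861	pGL4-SV40	RPKM	30.92	1220
plasmid	Ampicillin CDS	861	pBS/pEGFP-C1	RPKM	140.26	5535
plasmid	Kan/Neo CDS	795	pBS/pEGFP-C1	RPKM	140.57	5122
miRNA	miR-19b	1	phRL-SV40	RPM	14.40	812
miRNA	miR-19b	1	pGL4-SV40	RPM	26.49	1214
miRNA	miR-19b	1	pBS/pEGFP-C1	RPM	12.46	571
miRNA	miR-29a	1	phRL-SV40	RPM	17.85	1006
miRNA	miR-29a	1	pGL4-SV40	RPM	16.25	745
miRNA	miR-29a	1	pBS/pEGFP-C1	RPM	17.26	791
miRNA	miR-29b	1	phRL-SV40	RPM	25.86	1458
miRNA	miR-29b	1	pGL4-SV40	RPM	26.25	1203
miRNA	miR-29b	1	pBS/pEGFP-C1	RPM	21.99	1008
miRNA	miR-31	1	phRL-SV40	RPM	20.43	1152
miRNA	miR-31	1	pGL4-SV40	RPM	17.02	780
miRNA	miR-31	1	pBS/pEGFP-C1	RPM	12.48	572
miRNA	miR-125b	1	phRL-SV40	RPM	50.13	2826
miRNA	miR-125b	1	pGL4-SV40	RPM	49.92	2288
miRNA	miR-125b	1	pBS/pEGFP-C1	RPM	45.80	2099
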