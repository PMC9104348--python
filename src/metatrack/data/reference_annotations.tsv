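feature_id	name	adduct	mz_experimental	formula	retention_time_min	log2fc	q_value	confidence_level	lipid_class	source_table
78	oxobutanoic acid	[M-H]-	101.0245	C4H6O3	5.11	-0.36	0.03	2	polar	polar_panel
92	serine	[M-H]-	104.0354	C3H7NO3	8.71	-0.23	0.03	2	polar	polar_panel
159	threonine	[M-H]-	118.0509	C4H9NO3	8.35	-0.23	0.03	2	polar	polar_panel
242	ornithine	[M-H]-	131.0827	C5H12N2O2	8.85	-0.17	0.03	2	polar	polar_panel
251	malic acid	[M-H]-	133.0143	C4H6O5	7.1	-0.47	0.03	2	polar	polar_panel
345	oxoglutaric acid	[M-H]-	145.0143	C5H6O5	5.13	-0.28	0.04	2	polar	polar_panel
539	citrulline	[M-H]-	174.0883	C6H13N3O3	8.85	-0.17	0.03	2	polar	polar_panel
635	N-acetylglutamine	[M-H]-	187.0724	C7H12N2O4	4.9	0.26	0.04	2	polar	polar_panel
698	citric acid/isocitric acid	[M-H]-	191.0197	C6H8O7	6.67	-0.23	0.03	2	polar	polar_panel
807	tryptophan	[M-H]-	203.0824	C11H12N2O2	6.67	-0.31	0.03	2	polar	polar_panel
1742	bile acid derivative	[M-H]-	357.2796	C24H38O2	1.17	0.54	0.03	2	bile acid	polar_panel
1766	hydroxy-12-oxo-eicosatrienedioic acid	[M-H]-	365.1966	C20H30O6	1.19	-0.44	0.02	2	oxylipin	polar_panel
1780	bile acid derivative	[M-H]-	373.2744	C24H38O3	1.2	0.49	0.05	2	bile acid	polar_panel
1807	tetrahydroxy-12-oxo-tetraenoic acid	[M-H]-	381.1917	C20H30O7	1.1	-0.18	0.04	2	oxylipin	polar_panel
3968	20alpha-hydroxyprogesterone	[M+H]+	317.2476	C21H32O2	1.35	0.9		2	sterol	lipid_panel
2209	Cer(d41:1)	[M+CH3COOH-H]-	694.6365	C41H81NO3	7.36	0.12		2	Cer	lipid_panel
96	citrulline	[M-H]-	174.0885	C6H13N3O3	1.02	-0.22		2	polar	lipid_panel
473	FA(16:1)	[M-H]-	253.2174	C16H30O2	2.28	-0.01		2	FA	lipid_panel
1253	FA(28:0)	[M-H]-	423.4209	C28H56O2	6.89	-0.36		2	VLCFA	lipid_panel
4628	LPC(0:0_18:2)	[M+H]+	520.3401	C26H50NO7P	1.77	-0.25		2	LPC	lipid_panel
4738	LPC(20:4)	[M+H]+	544.3402	C28H50NO7P	1.81	-0.1		2	LPC	lipid_panel
5068	LPC(24:2)	[M+H]+	604.4336	C32H62NO7P	2.77	0.09		2	LPC	lipid_panel
1257	LPE(O-15:0)	[M-H]-	424.2851	C20H44NO6P	2.28	-0.07		2	LPE	lipid_panel
2668	PC(17:0_18:2)	[M+H2CO2-H]-	816.5782	C43H82NO8P	4.56	0.01		2	PC	lipid_panel
7098	PC(41:6)	[M+H]+	848.6162	C49H86NO8P	5.22	0.05		2	PC	lipid_panel
5785	PC(O-16:0_18:2)	[M+H]+	744.5903	C42H82NO7P	5.34	-0.18		2	PC O-	lipid_panel
6406	PC(O-38:2)	[M+H]+	800.6534	C46H90NO7P	6.55	-0.23		2	PC O-	lipid_panel
2297	PE(34:0)	[M-H]-	718.5404	C39H78NO8P	6.18	0.07		2	PE	lipid_panel
2475	PE(36:1)	[M-H]-	772.5873	C43H84NO8P	6.89	0.02		2	PE	lipid_panel
2406	PE(17:0_20:4)	[M-H]-	752.5243	C42H76NO8P	5.0	-0.16		2	PE	lipid_panel
5982	PE(18:0_20:4)	[M+H]+	768.5545	C43H78NO8P	5.24	-0.13		2	PE	lipid_panel
7279	PI(18:0_18:2)	[M+H]+	863.5644	C45H83O13P	4.56	-0.17		2	PI	lipid_panel
2543	SM(d36:1)	[M+H]+	731.6069	C41H83N2O6P	4.87	-0.16		2	SM	lipid_panel
2733	SM(d40:2)	[M+H2CO2-H]-	829.6458	C45H89N2O6P	6.2	-0.13		2	SM	lipid_panel
7627	TG(53:2)	[M+NH4]+	890.818	C56H104O6	9.08	-0.45		2	TG	lipid_panel
8173	TG(18:1_18:1_20:4)	[M+NH4]+	924.8022	C59H102O6	8.3	-0.19		2	TG	lipid_panel
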