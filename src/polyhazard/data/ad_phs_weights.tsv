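snp	chr	pos	gene	log_hr	neglog10_p	log_or_igap	log_or_igap_nogerad	a1
APOE_e2	19	NA	APOE	-0.47	15.0	-0.66	-0.49	e2
APOE_e4	19	NA	APOE	1.03	20.0	1.12	0.66	e4
rs4266886	1	207685786	CR1	-0.09	2.7	-0.1542	0.1520	T
rs61822977	1	207796065	CR1	-0.08	2.8	-0.0805	-0.0820	A
rs6733839	2	127892810	BIN1	-0.15	10.5	-0.1880	0.1807	T
rs10202748	2	234003117	INPP5D	-0.06	2.1	-0.058	-0.0603	A
rs115124923	6	32510482	HLA-DRB5	0.17	7.4	0.1216	-0.0973	A
rs115675626	6	32669833	HLA-DQB1	-0.11	3.2	-0.1246	0.1040	A
rs1109581	6	47678182	GPR115	-0.07	2.6	-0.0651	0.0601	T
rs17265593	7	37619922	BC043356	-0.23	3.6	-0.0659	-0.0620	T
rs2597283	7	37690507	BC043356	0.28	4.7	0.0679	0.0629	A
rs1476679	7	100004446	ZCWPW1	0.11	4.9	0.1741	0.0712	T
rs78571833	7	143122924	AL833583	0.14	3.8	0.0795	0.2083	A
rs12679874	8	27230819	PTK2B	-0.09	4.2	-0.0795	-0.0748	A
rs2741342	8	27330096	CHRNA2	0.09	2.9	0.0916	-0.0872	T
rs7831810	8	27430506	CLU	0.09	3.0	0.083	-0.0774	A
rs1532277	8	27466181	CLU	0.21	8.3	0.1385	-0.1271	T
rs9331888	8	27468862	CLU	0.16	5.1	0.0819	-0.0806	C
rs7920721	10	11720308	CR595071	-0.07	2.9	-0.0713	-0.0660	A
rs3740688	11	47380340	SPI1	0.07	2.8	0.0724	0.0739	T
rs7116190	11	59964992	MS4A6A	0.08	3.9	0.0991	-0.0968	A
rs526904	11	85811364	PICALM	-0.20	2.3	-0.1188	-0.1130	T
rs543293	11	85820077	PICALM	0.30	4.2	0.1257	-0.1192	A
rs11218343	11	121435587	SORL1	0.18	2.8	0.2697	0.2539	T
rs6572869	14	53353454	FERMT2	-0.11	3.0	-0.0947	0.1006	A
rs12590273	14	92934120	SLC24A4	0.10	3.5	0.1348	0.1231	T
rs7145100	14	107160690	abParts	0.08	2.0	0.1047	-0.1081	C
rs74615166	15	64725490	TRIP4	-0.23	3.1	-0.3358	-0.2986	T
rs2526378	17	56404349	BZRAP1	0.09	4.9	0.0762	0.0754	A
rs117481827	19	1021627	C19orf6	-0.09	2.5	-0.1288	-0.1059	T
rs7408475	19	1050130	ABCA7	0.18	4.3	0.0971	-0.0973	C
rs3752246	19	1056492	ABCA7	-0.25	8.4	-0.1345	-0.1308	C
rs7274581	20	55018260	CASS4	0.10	2.1	0.139	0.1497	A
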