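ko_id	definition	St0_0m	St0_SCM	St0_100m	St0_200m	St0_500m	St0_800m	St1_SCM	St1_100m	St1_200m	St1_500m	St1_800m	St4_0m	St4_SCM	St4_100m	St4_200m	St5_0m	St5_SCM	St5_100m	St5_200m
K00198	Anaerobic carbon-monoxide dehydrogenase catalytic subunit (EC:1.2.7.4)	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0
K05299	Formate dehydrogenase (NADP+) alpha subunit (EC:1.17.1.10)	15	19	18	8	72	64	9	27	12	81	83	12	1	9	28	11	13	63	81
K01938	Formate-tetrahydrofolate ligase (EC:6.3.4.3)	1877	1317	133	133	123	19	1359	1412	1221	125	1139	119	1251	1788	15	1857	1412	127	1149
K01491	Methylenetetrahydrofolate dehydrogenase (NADP+)/methenyltetrahydrofolate cyclohydrolase (EC:1.5.1.5 3.5.4.9)	1585	1398	1499	1268	1144	1188	1638	1557	1163	1194	126	1464	1553	1625	126	1678	161	1265	186
K00297	Methylenetetrahydrofolate reductase (NADPH) (EC:1.5.1.20)	1395	11	13	1123	16	149	15	133	125	1145	1199	126	1113	1355	922	1368	1178	981	954
K15023	5-Methyltetrahydrofolate corrinoid/iron sulfur protein methyltransferase (EC:2.1.1.258)	0	0	0	4	6	2	0	0	3	3	1	0	0	1	2	0	0	0	3
K14138	Acetyl-CoA synthase (EC:2.3.1.169)	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
K00197	Acetyl-CoA decarbonylase/synthase complex subunit gamma (EC:2.1.1.245)	0	0	0	0	0	1	0	0	0	1	0	0	0	0	0	0	0	0	0
K00194	Acetyl-CoA decarbonylase/synthase complex subunit delta (EC:2.1.1.245)	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
K00600	Glycine hydroxymethyltransferase (EC:2.1.2.1)	2815	1938	246	1775	1642	1759	2272	1968	1757	1857	1833	211	282	2113	1814	2882	2156	181	162
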