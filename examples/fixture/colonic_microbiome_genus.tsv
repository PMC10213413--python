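	colonic-R01	colonic-R02	colonic-R03	colonic-R04	colonic-R05	colonic-R06	colonic-R07	colonic-R08	colonic-R09	colonic-R10	colonic-R11	colonic-R12
colonic_g001	3679	1485	969	2703	2699	1702	272	155	90	68	274	116
colonic_g002	864	433	141	339	1107	240	59	51	23	16	73	18
colonic_g003	905	773	1652	1422	569	1152	65	310	88	65	77	120
colonic_g004	263	192	444	269	131	376	18	70	21	23	22	31
colonic_g005	1430	729	1082	406	931	643	34	30	26	121	49	115
colonic_g006	2547	1506	2353	1076	2359	1395	88	48	56	256	79	215
colonic_g007	934	1117	1546	532	1633	335	88	47	52	93	150	121
colonic_g008	240	602	463	632	522	266	272	33	102	125	18	26
colonic_g009	4498	2983	19107	2522	6802	10041	7556	22441	3441	2327	4547	3190
colonic_g010	2335	6588	3381	10717	4263	2197	5645	4424	5611	10760	2521	14707
colonic_g011	9044	1884	3574	1558	5915	1844	5192	2985	9052	8586	5835	1310
colonic_g012	291	895	512	656	715	481	3771	526	472	617	754	1217
colonic_g013	1478	675	190	792	142	213	831	677	539	442	1339	903
colonic_g014	1793	3689	702	1198	1137	1049	1041	610	4046	1673	712	1866
colonic_g015	342	371	419	465	1084	601	945	292	1386	436	362	410
colonic_g016	267	529	237	956	787	226	2101	229	341	503	822	814
colonic_g017	12736	5499	3299	10227	9599	5484	4521	4674	15026	2043	23424	9702
colonic_g018	1809	13238	3950	2572	2578	12858	6666	2803	3118	8297	2889	5468
colonic_g019	2628	4933	3070	3082	4970	3727	4436	7433	4554	4667	3277	7919
colonic_g020	1154	1355	1861	7017	1633	4439	6369	1936	1886	8819	2731	1606
colonic_hub_b2	763	524	1048	859	424	731	30	226	70	63	45	126
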