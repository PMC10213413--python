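	nasal-R01	nasal-R02	nasal-R03	nasal-R04	nasal-R05	nasal-R06	nasal-R07	nasal-R08	nasal-R09	nasal-R10	nasal-R11	nasal-R12
nasal_g001	1693	997	639	728	1766	443	25	56	14	25	69	28
nasal_g002	1005	882	609	442	1314	296	18	41	17	25	63	16
nasal_g003	645	337	640	633	219	384	7	167	49	29	18	29
nasal_g004	767	543	739	1038	380	650	7	150	55	42	41	60
nasal_g005	1618	706	1562	416	714	650	10	17	10	102	32	66
nasal_g006	770	712	1213	178	866	339	8	14	17	112	11	57
nasal_g007	328	679	2307	519	1182	921	24	27	188	48	30	20
nasal_g008	1869	419	626	1146	1082	1536	48	191	244	47	91	54
nasal_g009	3375	12272	9549	6034	5977	12448	9645	6928	11626	17189	8304	9713
nasal_g010	5843	5346	6471	4068	5528	5618	13385	9850	12236	7483	7947	10203
nasal_g011	1547	1298	2763	764	1005	1816	876	1371	904	431	1192	383
nasal_g012	3407	2389	1343	4111	1523	2143	1480	3255	1128	1812	5384	3508
nasal_g013	2754	1968	1153	2229	1490	1647	1371	2047	1340	1390	1429	1414
nasal_g014	526	1039	718	1684	85	423	671	2133	323	697	540	361
nasal_g015	1004	563	805	820	1411	1251	1246	2415	2197	1146	1412	1823
nasal_g016	755	2699	672	8564	513	1097	641	1211	457	1875	919	4042
nasal_g017	3204	9663	4288	4073	8059	3602	4979	14875	10539	3504	13021	2607
nasal_g018	7976	3309	7722	10005	7938	8240	7057	1583	3086	10301	7557	11406
nasal_g019	5079	1099	1262	808	2983	3609	846	1632	4013	2419	1333	996
nasal_g020	4192	1963	4123	837	4047	2205	7614	1898	1519	1287	521	3181
nasal_hub_b1	1643	1117	796	903	1918	682	42	139	38	36	86	33
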