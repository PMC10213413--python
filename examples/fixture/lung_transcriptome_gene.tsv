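	lung-R01	lung-R02	lung-R03	lung-R04	lung-R05	lung-R06	lung-R07	lung-R08	lung-R09	lung-R10	lung-R11	lung-R12
lung_gene0001	530	745	226	450	3786	224	54	107	31	14	239	50
lung_gene0002	4519	2895	813	909	8628	1751	340	549	139	61	1131	100
lung_gene0003	56	43	124	116	22	48	5	798	27	10	26	53
lung_gene0004	401	403	670	598	137	307	14	931	125	41	71	99
lung_gene0005	509	195	982	82	206	245	6	13	23	108	35	81
lung_gene0006	1243	1088	3403	245	1989	851	12	78	60	726	124	209
lung_gene0007	2608	3707	4097	3977	4748	2676	667	755	685	999	886	779
lung_gene0008	1048	1309	1316	1085	1150	880	240	362	418	275	228	240
lung_gene0009	1455	1724	1820	1116	1586	1718	203	633	344	261	526	539
lung_gene0010	1825	2596	1636	1529	1194	2332	275	588	513	505	470	225
lung_gene0011	754	1612	484	888	408	835	141	126	140	185	158	236
lung_gene0012	208	264	254	265	301	274	57	86	109	50	31	53
lung_gene0013	168	222	148	126	183	51	106	152	105	54	193	139
lung_gene0014	27	19	47	51	42	24	36	20	54	34	85	40
lung_gene0015	73	73	85	61	89	65	53	123	52	120	107	78
lung_gene0016	344	298	239	202	236	266	314	214	182	137	163	368
lung_gene0017	14	35	40	42	45	28	28	47	28	45	33	36
lung_gene0018	34	23	56	22	38	35	27	42	38	24	34	28
lung_gene0019	97	51	98	101	107	99	122	86	130	222	124	91
lung_gene0020	79	69	73	79	78	29	29	58	62	102	89	78
lung_gene0021	113	55	115	184	114	180	94	145	120	270	75	107
lung_gene0022	90	28	52	84	32	49	72	38	57	67	84	35
lung_gene0023	221	256	202	237	250	161	99	106	214	247	194	168
lung_gene0024	66	55	63	57	68	93	79	67	77	72	81	90
lung_gene0025	69	62	129	74	58	70	58	64	38	74	54	55
lung_gene0026	30	37	13	42	25	12	20	19	29	12	18	23
lung_gene0027	34	41	46	27	16	42	40	43	53	22	30	30
lung_gene0028	22	26	21	34	49	21	24	14	18	29	31	31
lung_gene0029	130	126	123	98	69	79	122	175	65	105	96	151
lung_gene0030	23	4	15	14	6	10	16	18	13	19	27	20
lung_gene0031	117	100	93	127	106	62	182	40	76	90	74	85
lung_gene0032	35	51	51	66	52	78	71	53	59	48	46	46
lung_gene0033	38	40	36	108	54	41	47	39	44	49	41	41
lung_gene0034	97	134	144	102	79	96	98	105	119	150	100	97
lung_gene0035	49	38	21	81	51	91	125	35	48	38	63	91
lung_gene0036	207	219	276	165	167	138	322	118	170	183	160	237
lung_gene0037	428	554	1104	1263	744	644	633	376	765	398	604	806
lung_gene0038	267	135	154	121	337	106	143	205	265	98	119	152
lung_gene0039	422	330	285	225	315	351	295	264	288	501	285	146
lung_gene0040	163	323	189	160	335	238	218	183	269	314	220	298
lung_hub_b3	3189	1061	2817	279	1518	396	10	94	26	104	185	144
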