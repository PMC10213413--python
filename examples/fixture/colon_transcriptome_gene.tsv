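	colon-R01	colon-R02	colon-R03	colon-R04	colon-R05	colon-R06	colon-R07	colon-R08	colon-R09	colon-R10	colon-R11	colon-R12
colon_gene0001	697	407	193	357	1409	345	70	121	17	17	104	20
colon_gene0002	225	180	64	78	712	46	24	20	3	1	57	11
colon_gene0003	204	129	559	326	158	291	6	1350	38	17	54	94
colon_gene0004	1238	946	2421	2318	637	1662	63	4710	485	134	366	624
colon_gene0005	1077	1115	2237	331	1758	492	31	68	26	289	51	250
colon_gene0006	245	190	1033	82	303	78	6	4	7	138	13	56
colon_gene0007	208	543	467	233	203	356	111	59	63	70	59	154
colon_gene0008	1199	2871	1229	1206	1246	1304	290	226	314	364	392	370
colon_gene0009	145	119	182	100	93	123	26	34	18	26	25	38
colon_gene0010	472	175	455	340	294	263	56	121	60	114	52	57
colon_gene0011	1560	3080	2147	1716	2571	1981	541	747	591	314	526	633
colon_gene0012	92	176	72	116	113	131	23	26	47	30	30	33
colon_gene0013	268	231	251	401	207	321	168	312	226	330	259	461
colon_gene0014	149	143	206	187	115	174	63	188	140	146	255	138
colon_gene0015	56	65	48	37	63	44	78	25	40	34	40	22
colon_gene0016	75	78	53	83	43	41	85	69	28	72	38	43
colon_gene0017	61	43	30	58	86	46	65	88	85	83	62	77
colon_gene0018	131	49	111	82	102	111	129	119	132	51	93	87
colon_gene0019	18	8	14	10	13	15	5	17	22	12	19	19
colon_gene0020	155	257	228	204	255	172	159	401	213	170	359	172
colon_gene0021	116	137	170	202	108	213	161	135	199	138	207	171
colon_gene0022	291	415	715	447	522	412	532	644	371	1139	791	487
colon_gene0023	205	196	216	206	132	142	137	134	95	127	187	157
colon_gene0024	23	29	32	15	13	15	20	19	24	15	29	22
colon_gene0025	225	250	307	383	244	382	392	215	194	230	289	273
colon_gene0026	37	34	26	28	36	23	51	53	34	35	39	36
colon_gene0027	79	88	55	93	69	74	65	66	114	57	79	112
colon_gene0028	185	121	198	236	252	259	231	196	410	230	387	247
colon_gene0029	65	40	39	53	63	27	28	52	63	51	36	39
colon_gene0030	75	86	37	69	82	110	97	79	72	97	90	71
colon_gene0031	65	116	91	85	62	69	85	67	100	83	131	102
colon_gene0032	88	54	59	91	59	54	47	37	46	48	46	61
colon_gene0033	73	51	54	58	173	84	97	66	124	61	46	146
colon_gene0034	232	282	144	183	257	161	168	244	94	152	128	131
colon_gene0035	93	78	106	113	56	148	99	97	71	41	49	66
colon_gene0036	119	119	120	124	88	118	86	156	110	53	109	143
colon_gene0037	130	62	74	135	77	125	118	88	43	109	92	73
colon_gene0038	363	338	346	471	315	347	331	317	471	288	317	309
colon_gene0039	144	85	196	105	156	135	126	146	117	179	187	101
colon_gene0040	20	35	38	30	24	23	9	8	22	9	19	17
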