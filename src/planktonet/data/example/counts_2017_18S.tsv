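	ASV0029	ASV0030	ASV0031	ASV0032	ASV0033	ASV0034	ASV0035	ASV0036	ASV0037	ASV0038	ASV0039	ASV0040	ASV0041	ASV0042	ASV0043	ASV0044	ASV0045	ASV0046	ASV0047	ASV0048	ASV0049	ASV0050	ASV0051	ASV0052	ASV0053	ASV0054	ASV0055	ASV0056	ASV0057	ASV0058	ASV0059	ASV0060	ASV0061	ASV0062	ASV0063	ASV0064	ASV0065	ASV0066	ASV0067	ASV0068	ASV0069	ASV0070	ASV0071	ASV0072	ASV0073	ASV0074	ASV0075	ASV0076	ASV0077	ASV0078	ASV0079	ASV0080	ASV0081	ASV0082	ASV0083	ASV0084	ASV0085	ASV0086	ASV0087	ASV0088	ASV0089	ASV0090	ASV0091	ASV0092	ASV0093	ASV0094	ASV0095	ASV0096	ASV0097	ASV0098	ASV0099	ASV0100	ASV0101	ASV0102	ASV0103	ASV0104	ASV0105	ASV0106	ASV0107	ASV0108	ASV0109	ASV0110	ASV0111	ASV0112	ASV0132	ASV0133	ASV0134	ASV0135	ASV0136	ASV0137	ASV0138	ASV0139	ASV0140	ASV0141	ASV0142	ASV0143	ASV0144	ASV0145	ASV0146	ASV0147	ASV0148	ASV0149	ASV0150	ASV_BRAARU
S2017.01.15m.0.2	2	0	63	232	2	3	15	0	56	78	0	73	27	61	718	7	79	866	57	63	4	0	16	42	0	33	21	258	1	0	0	8	5	140	10	124	0	1623	45	15	0	118	13	1	42	74	302	27	14	167	111	2972	19	213	21	48	403	88	8	0	83	0	549	898	457	348	621	6	15	5	261	5220	384	25	81	151	53	188	62	173	43	1	36	25	39	194	49	99	213	69	175	0	62	12	175	1152	144	35	0	173	0	0	0	36
S2017.01.15m.3.0	50	0	6	1267	17	6	34	0	1	4692	0	30	8	40	3099	7	44	729	13	0	17	0	2	7	0	1	29	135	6	0	0	132	215	9	30	101	0	2236	6	18	0	37	19	26	139	592	2633	546	56	8	1214	176	60	27	1	89	44	22	106	0	170	0	325	4	55	57	221	13	0	25	1554	12066	342	36	65	7	7	267	24	3	2	12	24	28	145	855	151	367	106	53	93	0	127	17	114	83	305	1363	0	111	0	0	0	52
S2017.02.15m.0.2	988	0	2	12	4	204	2	0	0	7	0	11	1	8	13	0	1471	25	12	0	0	0	2	1	0	0	2	0	2	0	0	540	0	6289	1	1	0	20	2	0	0	3	0	0	1	2	40	0	4	3	34	3	394	1	2	5277	0	0	9038	0	0	0	8	0	28	40	3	10459	2	5	52	29	52	8	755	0	1200	0	0	0	1	0	2	0	6	6	1	8	1	3	3	0	4	0	4	15	1	10	0	0	0	0	0	2
S2017.02.15m.3.0	1	0	0	0	0	0	0	0	1	0	0	2	0	697	0	0	0	0	2	1	0	0	441	0	0	0	2511	8	2277	0	0	7	1915	4	1606	9	0	0	0	3106	0	1	0	22594	3	24	0	1	0	2	1	0	0	0	1	1	0	3	2	0	0	0	0	0	14	2	0	0	1	1	3	0	1	4	1	2	1	0	2	1	0	2	0	2	6	2	22	4	5	5	33	0	1	0	7	2	1	0	0	0	0	0	0	1492
S2017.03.15m.0.2	2	0	4	50	67	2	80	0	115	70	0	33	1642	123	81	1201	42	110	69	196	159	0	1659	18	0	623	355	338	644	0	0	58	486	1	250	60	0	28	641	498	0	158	236	586	292	48	20	384	478	62	582	69	9	707	716	38	1074	60	39	0	66	0	455	839	470	451	2234	18	1672	203	848	19	293	1829	49	290	44	2928	171	507	132	17	163	65	120	321	1292	39	153	483	555	0	50	46	1045	66	198	272	0	931	0	0	0	3233
S2017.03.15m.3.0	681	0	249	498	10	530	7	0	4	228	0	7	25	0	168	30	198	254	19	33	7	0	0	69	0	12	1	47	1	0	0	37	0	716	0	183	0	829	1079	0	0	265	132	0	326	325	957	148	15	99	249	300	916	607	78	1939	97	29	1815	0	205	0	31	190	239	679	46	743	13	13	380	102	28	256	156	48	1265	82	77	11	1	16	75	11	21	217	99	27	976	205	4159	0	124	209	100	260	63	135	0	79	0	0	0	1
S2017.04.15m.0.2	1	0	11	130	15	1	0	0	51	32	0	38	19	241	3425	482	0	153	39	18	1	0	16	0	0	73	96	153	2	0	0	1	5	10	0	58	0	15663	92	48	0	74	15	26	26	102	51	6	234	95	77	39	4	111	1306	7	294	300	5	0	48	0	535	30	202	60	182	7	706	16	398	311	33	54	2	230	54	932	25	190	13	79	34	61	15	12	16	47	143	11	1213	0	147	26	41	3	6	69	0	1036	0	0	0	87
S2017.04.15m.3.0	20	0	16	0	9	164	1	0	25	0	0	196	1	1	1	63	104	0	5	3	8	0	2	37	0	3	41	675	8	0	0	234	6	62	34	425	0	1	308	158	0	96	27	53	118	180	2	24	258	85	54	0	461	59	5	350	254	42	298	0	227	0	1	27	8	649	68	161	92	44	1738	0	39	94	469	170	782	353	35	211	10	13	50	6	267	708	52	69	1734	12859	179	0	164	78	537	83	19	1093	0	336	0	0	0	2
S2017.05.15m.0.2	0	0	42	441	47	2	29	0	88	164	0	147	39	0	1320	52	12	8701	13	171	5	0	0	5	0	185	7	12	0	0	0	1	0	1	0	15	0	1187	43	0	0	116	29	2	45	7	414	3	58	109	51	795	6	372	822	0	112	61	3	0	156	0	2683	55	44	883	57	11	2698	24	124	2572	71	135	29	3308	48	268	53	194	5	37	86	16	86	18	64	9	221	63	178	0	28	4	487	257	107	121	0	915	0	0	0	0
S2017.05.15m.3.0	1775	0	35	14	9	145	11	0	1	0	0	10	11	5	92	10	30	26	28	5	1	0	0	13	0	1	6	31	1	0	0	1577	1	2993	2	351	0	8	263	3	0	1007	23	3	344	1546	13	6	98	86	56	10	3388	183	23	281	25	13	667	0	34	0	355	73	1852	40	114	131	164	52	498	23	666	95	194	23	365	222	26	20	35	195	53	23	120	68	196	2231	300	42	98	0	110	37	27	1509	125	42	0	2516	0	0	0	0
S2017.06.15m.0.2	11	0	287	110	164	5	188	0	1137	23	0	28	77	67	27	15	21	11	165	3138	52	0	38	22	0	504	2	21	5	0	0	14	4	27	2	129	0	8	44	3	0	24	105	13	105	15	8	0	18	42	111	3	44	454	1154	261	144	624	48	0	73	0	15	421	2832	5097	289	67	8011	489	6834	35	80	49	108	303	205	1440	254	127	209	36	927	42	74	377	572	442	478	171	30	0	25	131	221	115	501	1047	0	715	0	0	0	24
S2017.06.15m.3.0	3	0	42	63	187	1	2	0	109	40	0	11	119	2167	48	10	1	141	39	30	7	0	1475	153	0	17	230	83	112	0	0	65	2529	1	923	14	0	41	29	242	0	37	5	661	60	67	2	2	27	123	70	121	13	803	1103	24	710	376	59	0	21	0	110	24	139	43	217	25	20	218	330	621	148	52	2	56	126	136	284	23	41	74	21	584	15	2	100	44	310	77	300	0	40	83	699	149	125	66	0	8	0	0	0	7449
S2017.07.15m.0.2	924	0	3	157	16	1148	12	0	0	2253	0	4	14	8	48	13	3736	135	1	0	2	0	1	4	0	1	3	8	0	0	0	490	2	497	0	0	0	30	7	0	0	1	0	1	1	3	1	2	3	3	7	63	118	1	8	3257	6	0	1553	0	0	0	14	6	32	64	8	3603	0	22	27	371	125	4	13610	3	10920	22	12	3	18	0	52	5	2	7	24	3	5	5	8	0	1	1	0	1	2	2	0	21	0	0	0	3
S2017.07.15m.3.0	18	0	0	6	0	12	1	0	4672	13	0	0	0	6	3	0	3	20	0	12261	0	0	25	0	0	832	2	0	3	0	0	4	1	5	4	0	0	5	0	0	0	0	0	10	0	1	43	1	0	0	0	2	5	1	3917	7	0	184	6	0	0	0	3	1	4	0	0	46	476	0	2	71	1	0	5	534	74	1	0	0	0	0	4	1	0	0	2	0	0	10	3	0	0	1	0	1	0	4	0	0	0	0	0	0
S2017.08.15m.0.2	1143	0	8	5	15	3487	11	0	10	0	0	20	0	1	5	0	3639	5	2	8	0	0	0	13	0	20	0	0	0	0	0	24	0	7029	0	0	0	3	5	0	0	1	0	0	0	3	1	1	0	14	0	0	1029	1	6	1407	8	0	3939	0	0	0	1	2	1	2	13	5479	1	7	14	1	21	70	985	3	1610	2	3	0	1	2	4	2	1	4	0	12	0	2	0	0	0	0	2	0	0	46	0	9	0	0	0	0
S2017.08.15m.3.0	1	0	23	29	14	0	53	0	764	100	0	65	33	519	17	4	0	28	7	21899	1	0	113	41	0	117	241	24	33	0	0	0	43	0	42	37	0	4	0	7	0	6	1	84	8	3	5	0	1	1	0	2	0	2	2414	0	1	500	0	0	4	0	17	1	22	7	26	0	5470	2	504	26	121	2	1	365	0	38	2	4	4	3	20	4	7	7	9	5	27	18	18	0	20	19	30	17	4	3	0	86	0	0	0	59
S2017.09.15m.0.2	8	0	16	1214	10	4	5	0	3	678	0	173	2	19	349	18	3	30064	21	3	3	0	3	34	0	0	0	7	0	0	0	0	2	0	0	0	0	14	2	0	0	0	0	0	23	0	21	0	1	0	3	24	15	14	0	8	0	0	2	0	1	0	169	25	6	7	44	10	0	32	79	2003	82	32	15	9	2	69	9	23	108	20	10	10	0	7	8	5	11	15	2	0	7	3	22	27	2	20	0	16	0	0	0	0
S2017.09.15m.3.0	3026	0	31	2	1	1518	2	0	220	1	0	20	5	8	10	8	7646	54	73	64	14	0	11	26	0	183	2	22	0	0	0	64	8	4325	3	6	0	0	72	1	0	24	0	0	2	11	1	3	26	4	21	0	826	2	105	1244	51	22	691	0	2	0	1	7	16	46	36	1383	53	33	69	18	77	186	506	340	3314	17	11	19	41	6	4	17	21	402	38	14	27	17	39	0	34	1	27	30	33	166	0	49	0	0	0	0
S2017.10.15m.0.2	79	0	2249	118	1000	7	248	0	1	52	0	1812	510	3820	753	1278	151	1045	969	5	933	0	2305	2051	0	9	52	37	1113	0	0	0	44	1	50	27	0	45	83	12	0	298	58	28	42	84	6	11	137	290	116	18	1	146	0	4	899	0	3	0	51	0	11	936	1965	618	1030	2	1	2870	1228	360	1485	994	6	47	7	702	468	80	612	38	306	1188	965	592	1394	8	846	213	2329	0	116	56	202	502	117	907	0	160	0	0	0	53
S2017.10.15m.3.0	1227	0	4	6	23	5455	49	0	575	13	0	113	9	78	81	35	1164	91	77	1673	9	0	0	11	0	345	1	0	1	0	0	17	1	947	1	12	0	32	87	1	0	32	8	4	7	27	1	0	6	21	8	39	33	95	170	212	17	231	322	0	35	0	11	33	86	26	79	218	676	28	1475	148	141	13	282	488	176	115	2	5	17	13	26	1	35	7	56	194	515	237	19	0	8	2	35	12	4	130	0	172	0	0	0	0
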