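	ASV0029	ASV0030	ASV0031	ASV0032	ASV0033	ASV0034	ASV0035	ASV0036	ASV0037	ASV0038	ASV0039	ASV0040	ASV0041	ASV0042	ASV0043	ASV0044	ASV0045	ASV0046	ASV0047	ASV0048	ASV0049	ASV0050	ASV0051	ASV0052	ASV0053	ASV0054	ASV0055	ASV0056	ASV0057	ASV0058	ASV0059	ASV0060	ASV0061	ASV0062	ASV0063	ASV0064	ASV0065	ASV0066	ASV0067	ASV0068	ASV0069	ASV0070	ASV0071	ASV0072	ASV0073	ASV0074	ASV0075	ASV0076	ASV0077	ASV0078	ASV0079	ASV0080	ASV0081	ASV0082	ASV0083	ASV0084	ASV0085	ASV0086	ASV0087	ASV0088	ASV0089	ASV0090	ASV0091	ASV0092	ASV0093	ASV0094	ASV0095	ASV0096	ASV0097	ASV0098	ASV0099	ASV0100	ASV0101	ASV0102	ASV0103	ASV0104	ASV0105	ASV0106	ASV0107	ASV0108	ASV0109	ASV0110	ASV0111	ASV0112	ASV0132	ASV0133	ASV0134	ASV0135	ASV0136	ASV0137	ASV0138	ASV0139	ASV0140	ASV0141	ASV0142	ASV0143	ASV0144	ASV0145	ASV0146	ASV0147	ASV0148	ASV0149	ASV0150	ASV_BRAARU
S2016.01.15m.0.2	21	9	307	410	31	29	7	53	38	19	172	117	15	4372	457	6	160	54	61	48	4	30	1073	38	0	3	3437	0	243	0	9	4	1035	21	3626	35	21	54	24	1216	140	44	5	289	0	73	16	3	0	16	0	21	52	305	98	134	0	33	16	22	63	0	61	0	821	0	35	3	12	1	1147	477	2308	118	56	58	47	0	5	24	9	0	102	0	67	147	43	66	0	52	104	1465	7	16	236	0	26	89	5	192	2	154	0	173
S2016.01.15m.3.0	17	55	270	2729	17	32	16	37	1	845	55	26	9	130	62	3	105	1411	12	1	9	122	13	26	0	0	46	0	323	0	8	478	43	138	20	48	21	1141	134	3	8	66	14	47	0	150	5623	361	0	151	0	129	79	72	0	102	0	3	108	168	5	0	659	0	113	0	167	254	0	24	48	207	99	130	18	0	1	0	53	34	52	0	38	0	108	170	71	23	0	93	225	299	21	36	214	0	321	203	19	667	306	830	0	167
S2016.02.15m.0.2	9	339	60	21	20	0	24	108	660	22	246	484	57	128	104	209	54	11	128	2103	153	392	191	140	0	3191	16	0	201	0	53	5	677	20	68	60	178	509	233	801	669	213	14	185	0	121	98	15	0	277	0	27	48	43	3321	34	0	3125	42	822	81	0	102	0	190	0	379	11	4681	113	6788	38	271	46	8	631	6	0	40	94	20	0	55	0	3479	339	92	264	0	335	2804	1443	119	34	90	0	79	153	9	1251	115	48	0	1453
S2016.02.15m.3.0	24	52	23	1	5	29	3	24	1090	11	8	53	6	288	68	35	19	4	16	508	1	4	1029	13	0	16	1403	0	685	0	3	126	808	70	5458	58	34	136	34	259	239	592	21	761	0	158	43	8	0	0	0	10	79	6	458	95	0	63	13	45	3	0	18	0	130	0	221	33	12	5	34	411	21	51	59	291	159	0	3	2	10	0	6	0	88	87	14	38	0	100	2051	495	3	30	10	0	11	89	9	91	9	13	0	162
S2016.03.15m.0.2	23	2	0	801	15	0	0	4	3	155	24	2	0	20	362	5	91	25102	2	12	0	0	5	1	0	2	7	0	0	0	3	22	3	7	3	2	2	1671	10	0	0	5	0	0	0	2	2944	2	0	16	0	143	62	71	407	9	0	25	21	8	12	0	1398	0	13	0	8	55	38	3	9	528	3	3	54	11	77	0	13	3	25	0	6	0	2	7	5	0	0	7	64	1	1	0	7	0	4	11	0	3	6	1	0	4
S2016.03.15m.3.0	0	1	0	34	0	0	2	1	0	59	0	7	0	449	46	16	2	3	1	0	0	0	229	26	0	0	2484	0	990	0	3	80	4161	13	15852	7	4	185	4	362	2	31	7	4950	0	48	253	5	0	8	0	146	7	3	0	28	0	5	11	30	1	0	13	0	6	0	1	1	0	1	4	78	0	1	0	0	41	0	0	3	1	0	4	0	2	2	16	18	0	21	12	2	1	0	23	0	0	83	9	38	4	2	0	483
S2016.04.15m.0.2	6	558	30	1215	31	5	40	75	70	127	22	189	32	1322	315	9	2	80	63	120	70	142	16	51	0	66	41	0	82	0	39	6	138	4	68	1201	84	458	602	21	59	148	92	155	0	267	727	10	0	73	0	140	33	3372	772	8	0	266	8	1200	191	0	91	0	2172	0	360	42	414	164	2691	1131	521	138	4	1057	27	0	95	347	79	0	257	0	189	106	425	16	0	412	104	51	74	24	350	0	56	72	24	431	129	81	0	255
S2016.04.15m.3.0	23	144	9	93	216	42	292	45	65	139	972	21	42	79	181	42	96	173	12	17	16	16	2	26	0	2	34	0	1541	0	142	266	29	43	4	277	783	3556	272	5	13	742	417	253	0	480	1424	143	0	600	0	297	820	250	32	57	0	624	696	1252	16	0	563	0	646	0	997	81	16	117	101	644	82	114	209	18	785	0	126	20	19	0	111	0	31	237	890	47	0	180	363	302	200	59	126	0	310	128	37	203	590	108	0	76
S2016.05.15m.0.2	4	221	21	581	1	0	6	11	18	207	39	3	2	109	566	3	14	9108	49	3	1	2	1044	45	0	6	25	0	240	0	6	1	451	3	2358	9	4	3161	6	166	2	869	5	54	0	9	1512	1	0	45	0	501	10	13	23	15	0	34	9	359	0	0	1696	0	181	0	32	1	164	28	26	3088	107	4	8	27	8	0	10	5	13	0	68	0	4	20	5	1	0	23	688	6	27	6	5	0	3	39	1	141	3	68	0	14
S2016.05.15m.3.0	0	32	256	23	8	0	5	182	23	3	224	172	29	301	136	20	12	19	3	28	2	30	79	50	0	17	301	0	9	0	45	30	453	62	24	43	10	10	1767	67	117	1124	38	607	0	193	207	1	0	122	0	30	105	159	6442	154	0	837	4	110	51	0	62	0	493	0	147	240	291	66	1007	23	1391	1173	123	180	30	0	62	199	60	0	540	0	73	67	266	27	0	766	2084	978	65	57	1002	0	116	681	190	1505	42	75	0	15
S2016.06.15m.0.2	0	68	135	1	7	0	10	48	4	0	29	12	34	26407	4	1	0	1	37	0	11	28	3311	35	0	0	103	0	264	0	7	1	454	0	461	3	6	0	0	118	2	135	1	2299	0	32	0	1	0	10	0	1	0	4	0	1	0	0	0	68	13	0	0	0	438	0	124	0	0	90	37	2	26	8	0	15	1	0	86	20	148	0	70	0	10	4	13	11	0	37	33	13	33	8	31	0	25	45	51	8	6	6	0	1782
S2016.06.15m.3.0	33	56	10	8	295	12	27	343	206	83	838	12	516	12	25	74	43	23	1560	2760	55	6	2	78	0	997	12	0	8	0	340	18	4	93	8	135	6	622	41	0	126	147	311	9	0	552	36	129	0	157	0	12	100	514	1119	224	0	878	276	1040	97	0	122	0	1011	0	371	16	466	294	1636	156	914	136	83	3791	14	0	58	47	34	0	300	0	72	189	951	71	0	694	307	248	95	7	249	0	286	340	142	1253	62	328	0	33
S2016.07.15m.0.2	2458	25	28	230	39	2207	14	68	45	68	10	9	0	2	105	5	529	1515	31	158	65	223	0	7	0	37	0	0	0	0	1	14	0	123	1	1	10	19	4	0	0	1	1	0	0	2	141	0	0	4	0	42	55	61	188	621	0	31	436	27	16	0	146	0	55	0	87	22818	100	42	5676	1399	56	25	1860	236	4424	0	6	63	22	0	427	0	261	2	7	6	0	9	7	29	1	14	10	0	2	46	1	106	6	4	0	0
S2016.07.15m.3.0	11	3	5	3335	14	22	3	30	10	633	42	7	3	64	114	2	304	5166	1	48	3	25	116	5	0	4	20	0	39	0	5	7	147	52	381	1	0	1351	0	4	0	2	0	638	0	6	201	1	0	3	0	383	42	0	0	213	0	36	241	8	1	0	6605	0	9	0	0	59	7	18	67	5334	50	0	74	4	273	0	6	3	14	0	9	0	6	3	4	21	0	7	42	9	0	0	13	0	13	2	2	8	6	21	0	23
S2016.08.15m.0.2	0	7	70	229	6	2	31	24	10	13508	21	101	33	2	107	12	0	6630	114	59	27	20	2	10	0	39	0	0	0	0	0	0	0	0	0	1	5	39	32	0	21	0	1	0	0	3	19	0	0	2	0	59	0	4	3	1	0	33	0	17	1	0	294	0	11	0	22	3	38	9	546	1851	9	124	1	42	0	0	185	16	81	0	30	0	14	14	29	0	0	74	31	22	5	10	11	0	2	5	2	3	15	2	0	0
S2016.08.15m.3.0	34	870	187	82	94	8	679	1095	87	66	4904	477	293	70	535	707	106	1402	568	831	708	9	13	224	0	22	3	0	2	0	67	2	0	4	1	8	40	450	46	1	192	229	58	0	0	192	24	5	0	36	0	3	1	58	46	102	0	89	9	537	62	0	69	0	309	0	73	24	47	93	5035	206	3003	407	36	73	16	0	89	137	224	0	507	0	175	348	933	104	0	437	1921	1943	506	60	700	0	141	53	359	87	630	919	0	13
S2016.09.15m.0.2	2640	40	140	553	8	243	5	5	41	421	305	110	14	15885	175	105	1602	30	37	10	40	12	424	8	0	2	336	0	23	0	1	17	59	9	35	3	7	10	12	31	1	6	9	8	0	5	9	2	0	8	0	9	1824	139	1	37	0	5	43	53	45	0	21	0	71	0	54	303	5	42	19	1424	7	21	2665	3	238	0	104	78	83	0	7	0	4	29	22	7	0	30	9	31	196	5	326	0	14	24	2	71	17	2	0	637
S2016.09.15m.3.0	518	142	344	4	18	161	6	68	705	2	3295	141	253	378	5	38	130	17	202	496	167	118	265	92	0	375	11	0	13	0	62	26	39	88	24	39	150	7	831	6	9	293	15	68	0	21	0	3	0	9	0	0	143	32	655	713	0	3526	484	22	9	0	0	0	305	0	276	717	296	317	5936	2	597	6798	108	768	291	0	75	94	114	0	11	0	231	383	405	181	0	103	487	408	5	46	213	0	91	155	177	514	37	25	0	18
S2016.10.15m.0.2	23151	108	643	4	8	2256	80	135	20	13	84	129	14	155	25	56	521	5	74	3	16	23	491	39	0	4	157	0	44	0	8	28	927	669	4	26	30	1	18	15	6	31	6	74	0	5	0	0	0	16	0	3	5467	174	13	395	0	6	206	253	15	0	0	0	242	0	3404	1385	3	144	837	11	57	550	682	29	221	0	13	28	51	0	1	0	13	9	282	80	0	34	127	25	9	15	177	0	8	39	17	125	7	13	0	22
S2016.10.15m.3.0	64	0	3	0	1	77	0	0	628	0	17	2	0	42	0	4	4	1	1	3438	0	2	8	1	0	279	4	0	0	0	0	0	6	2	5	0	0	0	1	1	0	1	0	16	0	2	0	0	0	0	0	0	1	0	13204	9	0	968	12	7	1	0	0	0	11	0	1	5	614	1	18	0	0	8	1	2559	80	0	0	0	3	0	0	0	0	0	4	0	0	0	2	2	3	3	0	0	7	2	0	2	0	0	0	0
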