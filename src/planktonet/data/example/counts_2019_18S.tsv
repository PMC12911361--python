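	ASV0029	ASV0030	ASV0031	ASV0032	ASV0033	ASV0034	ASV0035	ASV0036	ASV0037	ASV0038	ASV0039	ASV0040	ASV0041	ASV0042	ASV0043	ASV0044	ASV0045	ASV0046	ASV0047	ASV0048	ASV0049	ASV0050	ASV0051	ASV0052	ASV0053	ASV0054	ASV0055	ASV0056	ASV0057	ASV0058	ASV0059	ASV0060	ASV0061	ASV0062	ASV0063	ASV0064	ASV0065	ASV0066	ASV0067	ASV0068	ASV0069	ASV0070	ASV0071	ASV0072	ASV0073	ASV0074	ASV0075	ASV0076	ASV0077	ASV0078	ASV0079	ASV0080	ASV0081	ASV0082	ASV0083	ASV0084	ASV0085	ASV0086	ASV0087	ASV0088	ASV0089	ASV0090	ASV0091	ASV0092	ASV0093	ASV0094	ASV0095	ASV0096	ASV0097	ASV0098	ASV0099	ASV0100	ASV0101	ASV0102	ASV0103	ASV0104	ASV0105	ASV0106	ASV0107	ASV0108	ASV0109	ASV0110	ASV0111	ASV0112	ASV0132	ASV0133	ASV0134	ASV0135	ASV0136	ASV0137	ASV0138	ASV0139	ASV0140	ASV0141	ASV0142	ASV0143	ASV0144	ASV0145	ASV0146	ASV0147	ASV0148	ASV0149	ASV0150	ASV_BRAARU
S2019.01.15m.0.2	0	0	17	214	21	2	2	10	17	1924	0	339	68	139	711	0	0	8194	5	24	0	2	347	1	3	65	415	0	19	31	6	2	539	0	17	11	205	9819	9	89	93	0	18	21	0	10	82	16	12	19	80	823	0	22	2869	1	0	346	0	98	3	8	449	0	50	36	0	0	485	11	0	462	72	9	2	251	0	6	97	8	17	0	67	0	0	10	194	28	295	21	217	167	52	9	8	0	76	56	0	41	80	0	78	203
S2019.01.15m.3.0	6	0	41	634	207	0	9	389	0	82	0	193	23	49	2081	0	6	430	15	2	0	8	2	62	15	0	12	0	5	359	18	3	3	0	9	293	579	4117	24	6	247	0	23	71	0	558	5913	125	79	133	370	198	9	129	13	2	0	51	6	425	7	215	114	0	748	166	0	2	16	379	0	1388	42	135	7	4	3	344	20	71	71	0	184	0	0	393	127	222	7329	688	677	457	66	50	812	0	108	585	0	9112	128	0	580	5
S2019.02.15m.0.2	2592	0	107	2	140	76	11	61	786	16	0	1090	163	24	10	0	381	16	956	241	0	223	10	8	11	366	6	0	12	100	5	73	15	82	1	835	139	199	25	20	136	0	8	2	0	1168	25	16	58	21	2656	1	65	167	1029	335	0	1842	153	11238	72	149	1	0	425	840	0	169	36	72	0	2	92	69	225	1312	331	1969	185	206	20	0	45	0	0	177	118	101	72	275	387	74	25	123	473	0	144	605	0	244	313	0	667	12
S2019.02.15m.3.0	0	0	52	1	49	0	0	53	407	0	0	290	55	6	1	0	0	1	39	1933	0	8	23	8	105	758	730	0	6	228	106	0	10	2	149	120	55	20	194	123	597	0	4	23	0	667	0	20	26	164	134	0	0	273	10809	0	0	5943	0	13	19	47	0	0	79	400	0	0	2578	19	0	1	81	72	0	1570	1	60	11	46	2	0	20	0	0	731	278	36	84	163	245	565	52	73	378	0	126	429	0	749	56	0	162	34
S2019.03.15m.0.2	1868	0	5	0	5	281	0	6	0	0	0	4	0	183	0	0	255	0	1	0	0	6	33	2	2	4	216	0	53	21	1	242	307	2497	353	19	3	0	14	35	24	0	8	74	0	24	0	14	21	25	210	0	1079	59	15	468	0	12	7571	140	13	10	0	0	192	44	0	544	3	3	0	0	1	29	197	2	4763	43	0	31	9	0	2	0	0	1	53	11	168	3	0	10	4	1	10	0	14	4	0	35	29	0	2	46
S2019.03.15m.3.0	36	0	1	431	1	55	0	21	0	73	0	3	0	18	77	0	14	2108	1	3	0	0	32	3	0	0	315	0	40	2	4	101	161	48	690	20	3	19327	5	39	5	0	16	236	0	13	1321	6	3	1	32	280	1	28	6	83	0	0	30	27	3	2	1478	0	15	20	0	22	0	27	0	1007	2	1	68	3	78	24	1	0	2	0	0	0	0	31	8	1	153	19	102	1	75	0	3	0	0	71	0	6	1	0	27	10
S2019.04.15m.0.2	2465	0	3	2	12	305	0	117	44	4	0	22	7	1642	0	0	1031	0	5	2	0	19	566	15	4	37	1258	0	21	116	4	338	73	935	627	27	119	0	7	10	38	0	12	118	0	93	1	0	48	72	10	1	542	543	2108	2187	0	498	4758	493	273	544	0	0	723	428	0	3011	170	172	0	0	338	3	570	1912	294	31	1	11	6	0	23	0	0	25	258	105	368	14	263	293	23	1	2	0	12	54	0	33	10	0	30	439
S2019.04.15m.3.0	3	0	58	25	35	3	10	572	143	120	0	72	92	14	78	0	9	5	13	167	0	32	16	21	93	123	255	0	101	50	452	40	49	85	186	233	144	367	262	13	290	0	269	23	0	351	1246	33	114	348	391	121	3	328	1118	11	0	1956	74	167	139	109	16	0	163	1186	0	10	204	355	0	153	94	379	15	545	7	2111	190	109	160	0	59	0	0	20	221	62	7345	1222	657	148	75	173	119	0	90	306	0	423	66	0	528	1712
S2019.05.15m.0.2	28	0	251	7	29	0	5	76	229	13	0	8	23	140	4	0	5	21	5	343	0	1	76	23	92	330	284	0	93	3	11	2	218	23	60	17	68	46	46	19	2	0	1	71	0	34	14	7	9	1	44	3	4	24	32634	42	0	275	5	180	12	8	10	0	193	92	0	15	1021	105	0	3	41	15	40	594	23	780	85	6	7	0	17	0	0	52	155	19	81	70	33	78	6	20	14	0	9	31	0	77	8	0	227	351
S2019.05.15m.3.0	11	0	89	2	48	36	147	990	0	2	0	22	11	425	1	0	77	5	33	0	0	0	388	5	232	0	571	0	748	91	431	98	2894	40	1217	68	76	173	251	58	34	0	148	1658	0	594	6	89	7	60	125	16	66	238	0	153	0	5	316	1514	47	528	13	0	1240	120	0	11	0	111	0	0	123	145	138	0	133	3345	145	79	64	0	75	0	0	217	194	16	651	375	381	263	542	21	52	0	160	112	0	978	114	0	349	213
S2019.06.15m.0.2	2	0	49	0	95	0	0	441	195	22	0	50	45	6309	0	0	3	8	140	13	0	83	424	141	7	29	65	0	64	61	39	19	779	4	796	1	9	1	64	558	23	0	10	1165	0	62	2	0	28	98	63	1	12	56	1331	18	0	38	182	79	42	635	18	0	1478	221	0	43	173	70	0	7	222	468	27	335	1	1532	394	54	266	0	44	0	0	216	222	39	105	105	100	7	38	29	28	0	178	15	0	1320	93	0	29	283
S2019.06.15m.3.0	45	0	3	0	2	189	2	1	0	0	0	0	0	5	0	0	50	0	0	0	0	1	1	0	1	0	22	0	1	5	1	17	0	539	0	0	0	0	5	3	0	0	1	0	0	0	0	0	0	9	1	0	451	2	0	1457	0	0	1119	17	0	10	0	0	7	59	0	499	0	5	0	0	7	5	812	0	12458	6	1	1	0	0	2	0	0	1	1	2	0	1	3	2	2	1	1	0	3	17	0	11	0	0	4	0
S2019.07.15m.0.2	821	0	9	7	4	3737	5	20	559	3	0	18	7	5	0	0	588	13	4	158	0	2	0	1	13	1791	0	0	0	1	0	28	0	23	1	0	0	0	0	0	0	0	1	0	0	0	0	0	1	3	0	0	351	0	1680	1188	0	126	395	18	2	3	3	0	4	6	0	1092	449	32	0	4	16	8	2099	1323	1165	7	0	14	2	0	3	0	0	8	0	1	3	2	1	0	0	3	6	0	3	3	0	1	1	0	13	1
S2019.07.15m.3.0	36	0	20	366	42	82	2	243	21	83	0	85	36	307	726	0	23	259	0	20	0	11	2707	37	32	26	362	0	556	25	9	24	943	70	661	3	8	289	16	109	23	0	3	200	0	11	26	0	8	10	10	43	477	1	235	2944	0	60	863	36	1	55	71	0	91	61	0	908	767	159	0	1510	1119	54	185	209	3642	40	13	7	35	0	16	0	0	4	120	264	35	35	49	40	117	15	20	0	117	35	0	223	12	0	14	707
S2019.08.15m.0.2	45	0	3908	0	712	20	103	341	7964	35	0	54	553	14	5	0	89	4	132	5033	0	195	9	461	227	1732	5	0	1	28	24	11	0	0	0	12	6	0	188	2	12	0	12	10	0	293	1	2	9	16	16	1	11	205	1263	6	0	482	0	63	84	42	4	0	2396	904	0	338	337	295	0	26	216	236	78	810	443	3287	172	20	712	0	1219	0	0	50	37	162	139	16	97	71	211	58	28	0	58	182	0	180	28	0	191	0
S2019.08.15m.3.0	1	0	0	11	1	0	2	2	2	51	0	4	2	20337	50	0	3	39	9	9	0	0	6300	2	0	0	2245	0	924	7	0	1	8404	1	95	0	1	0	5	1391	0	0	0	488	0	4	7	2	1	2	1	33	0	13	3	4	0	4	0	8	2	6	73	0	40	19	0	1	23	3	0	110	35	1	1	4	0	9	0	0	5	0	14	0	0	12	18	2	7	11	11	3	0	0	1	0	0	2	0	348	8	0	3	79
S2019.09.15m.0.2	22	0	20	1258	15	1	97	34	17	5005	0	18	4	251	1320	0	17	3694	14	40	0	4	5	44	1	10	1	0	13	1	1	1	0	0	0	0	0	307	6	2	1	0	0	2	0	12	134	0	0	0	6	89	0	0	100	0	0	39	0	34	3	1	253	0	49	76	0	7	117	18	0	4707	9	30	10	28	2	37	4	4	13	0	3	0	0	29	23	10	46	39	2	3	1	2	1	0	8	1	0	67	7	0	3	3
S2019.09.15m.3.0	15	0	2	154	21	164	3	39	2	4	0	56	22	8628	107	0	20	121	2	3	0	64	9704	17	3	0	449	0	102	24	4	10	2822	5	1774	21	7	72	8	336	0	0	16	1456	0	1	50	5	9	3	1	13	30	3	1	51	0	0	9	21	1	3	20	0	70	41	0	5	2	94	0	462	7	54	19	2	164	83	16	2	63	0	16	0	0	13	10	7	2525	72	524	72	21	5	46	0	98	40	0	97	3	0	26	60
S2019.10.15m.0.2	2698	0	423	144	48	8235	817	584	14	111	0	514	230	8	91	0	1538	535	1143	10	0	54	19	260	23	3	6	0	1	27	8	24	1	60	0	26	4	115	40	0	4	0	191	0	0	57	7	12	44	166	182	19	859	1481	20	1341	0	21	460	391	103	33	7	0	220	96	0	970	1	1171	0	46	625	98	1481	86	2897	103	622	62	168	0	65	0	0	268	98	16	148	158	1079	254	121	69	184	0	231	108	0	20	155	0	182	7
S2019.10.15m.3.0	654	0	257	1271	24	518	379	16	103	782	0	198	116	544	1859	0	1329	3119	80	266	0	90	2355	161	145	98	45	0	738	86	54	112	116	8	309	431	39	217	12	22	11	0	29	20	0	22	463	11	67	20	39	331	369	90	196	634	0	10	47	135	11	23	178	0	633	412	0	266	36	4	0	1741	1186	191	709	943	261	1169	68	135	33	0	105	0	0	325	293	461	162	124	1524	1207	43	133	780	0	65	168	0	152	38	0	201	22
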