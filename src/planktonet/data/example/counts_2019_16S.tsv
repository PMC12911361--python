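	ASV0001	ASV0002	ASV0003	ASV0004	ASV0005	ASV0006	ASV0007	ASV0008	ASV0009	ASV0010	ASV0011	ASV0012	ASV0013	ASV0014	ASV0015	ASV0016	ASV0017	ASV0018	ASV0019	ASV0020	ASV0021	ASV0022	ASV0023	ASV0024	ASV0025	ASV0026	ASV0027	ASV0028	ASV0113	ASV0114	ASV0115	ASV0116	ASV0117	ASV0118	ASV0119	ASV0120	ASV0121	ASV0122	ASV0123	ASV0124	ASV0125	ASV0126	ASV0127	ASV0128	ASV0129	ASV0130	ASV0131	ASV_UCYNA
S2019.01.15m.0.2	289	8	637	323	74	417	148	2	133	14216	1871	37	706	0	17	233	134	0	57	7	98	68	1	0	14	3	26	0	212	0	57	10	5	21	0	0	667	14	296	0	52	329	10	46	20	0	14	44
S2019.01.15m.3.0	2286	95	5	519	2	200	122	58	5	4310	1	197	1604	0	2035	18	1588	0	36	130	3122	20	30	0	4	281	31	0	2418	0	2782	1704	513	1965	0	0	2325	1419	931	0	1302	1432	547	610	638	0	86	45
S2019.02.15m.0.2	156	607	4962	812	1023	561	560	619	291	379	4271	126	8655	0	179	5	1	0	2	27	2	146	45	0	1	8	24	0	1720	0	189	863	117	192	0	0	242	17	295	0	1240	165	148	35	201	0	257	69
S2019.02.15m.3.0	37	34	3062	77	5523	9	75	0	734	0	12955	304	324	0	49	47	0	0	39	14	2	295	10	0	2	5	7	0	316	0	595	81	105	14	0	0	92	47	219	0	348	48	44	187	140	0	6	171
S2019.03.15m.0.2	1105	37	752	1457	1139	338	506	8982	195	2	27	998	2744	0	265	10776	0	0	920	43	2	33	576	0	28	388	36	0	9661	0	384	166	168	140	0	0	80	221	174	0	9497	749	3025	37	1145	0	294	538
S2019.03.15m.3.0	2	0	0	24	4	14	31	201	2	14174	2	1	10	0	2	29	460	0	11	0	12641	4	1	0	11	0	0	0	7	0	16	3	1	6	0	0	47	6	11	0	31	12	4	3	8	0	6	0
S2019.04.15m.0.2	151	19	1668	40	18	24	340	13532	101	1	187	353	235	0	179	177	1	0	984	1	2	94	12	0	24	11	1	0	2040	0	32	179	27	71	0	0	215	11	52	0	86	465	73	14	10	0	80	121
S2019.04.15m.3.0	138	25	299	400	132	951	1371	78	324	170	601	466	319	0	51	105	15	0	1714	29	160	99	89	0	29	15	35	0	8128	0	630	551	151	346	0	0	2675	868	342	0	325	1054	910	698	471	0	632	1510
S2019.05.15m.0.2	1189	99	17329	833	3535	24	216	211	12023	790	2770	1138	551	0	234	225	7	0	3681	346	40	2166	41	0	81	16	39	0	874	0	228	237	8	308	0	0	270	163	304	0	262	54	18	203	112	0	29	421
S2019.05.15m.3.0	293	244	0	38	0	63	467	1294	0	48	0	763	308	0	311	1895	2	0	15027	774	29	0	168	0	1734	53	57	0	1949	0	1127	282	589	606	0	0	383	642	61	0	1826	1305	605	564	815	0	197	248
S2019.06.15m.0.2	1028	376	397	380	42	169	51	21	650	37	205	285	94	0	4026	1653	3	0	4474	496	17	210	362	0	727	246	9	0	7804	0	149	661	88	748	0	0	468	150	581	0	102	7572	397	45	103	0	5301	92
S2019.06.15m.3.0	10	1	1	76	0	38	101	49549	0	0	2	117	646	0	145	75	0	0	385	44	1	1	141	0	11	18	69	0	96	0	214	35	560	125	0	0	269	20	878	0	206	1737	96	21	147	0	319	78
S2019.07.15m.0.2	15	1	432	34	458	2	18	10128	2616	20	5291	24	140	0	54	18	13	0	30	57	10	379	20	0	0	5	122	0	209	0	48	0	4	18	0	0	156	5	80	0	163	117	15	5	9	0	18	10
S2019.07.15m.3.0	8	2	0	23	7	7	13	26	53	23	173	15	14	0	370	21373	976	0	5242	637	1039	271	117	0	1153	20	160	0	680	0	140	25	115	68	0	0	436	46	289	0	477	930	18	72	141	0	15	414
S2019.08.15m.0.2	108	42	1039	246	3733	184	1799	135	3945	2	9190	48	678	0	290	2	3	0	20	3857	19	5533	50	0	6	211	249	0	604	0	758	146	342	464	0	0	901	171	575	0	843	17	238	145	572	0	147	80
S2019.08.15m.3.0	2	0	0	0	0	1	0	0	0	12	0	2	9	0	4	19935	86	0	8698	0	78	1	1	0	1459	0	2	0	54	0	16	5	2	0	0	0	9	5	1	0	6	1	1	1	7	0	0	9
S2019.09.15m.0.2	155	57	709	10	88	19	46	4	943	9651	50	7	81	0	73	240	720	0	102	233	17547	151	708	0	61	40	10	0	632	0	80	5	24	83	0	0	38	77	7	0	1496	70	41	3	275	0	69	74
S2019.09.15m.3.0	50	2	1	16	0	0	3	18	0	58	1	2	20	0	479	15476	43	0	2984	22	199	3	9	0	2686	6	40	0	108	0	917	15	24	55	0	0	53	4	362	0	47	246	6	11	37	0	19	10
S2019.10.15m.0.2	251	39	19	138	13	417	39	441	11	78	75	168	1494	0	203	17	52	0	27	741	72	9	113	0	2	153	22	0	1154	0	537	213	60	135	0	0	4259	1819	1197	0	2379	745	220	286	2489	0	857	2845
S2019.10.15m.3.0	220	42	90	36	36	7	499	301	16	894	55	197	39	0	184	3812	400	0	267	109	3430	472	251	0	463	90	17	0	1338	0	4458	99	780	398	0	0	444	392	1815	0	2824	79	134	162	648	0	371	116
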