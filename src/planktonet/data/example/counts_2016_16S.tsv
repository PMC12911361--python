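	ASV0001	ASV0002	ASV0003	ASV0004	ASV0005	ASV0006	ASV0007	ASV0008	ASV0009	ASV0010	ASV0011	ASV0012	ASV0013	ASV0014	ASV0015	ASV0016	ASV0017	ASV0018	ASV0019	ASV0020	ASV0021	ASV0022	ASV0023	ASV0024	ASV0025	ASV0026	ASV0027	ASV0028	ASV0113	ASV0114	ASV0115	ASV0116	ASV0117	ASV0118	ASV0119	ASV0120	ASV0121	ASV0122	ASV0123	ASV0124	ASV0125	ASV0126	ASV0127	ASV0128	ASV0129	ASV0130	ASV0131	ASV_UCYNA
S2016.01.15m.0.2	136	102	1296	2393	38	3158	0	967	32	2334	488	294	0	2445	434	2112	44	98	536	39	583	33	12	0	99	12	7	139	1427	875	357	199	493	113	0	692	548	94	0	234	303	493	201	203	90	0	93	41
S2016.01.15m.3.0	571	81	0	127	0	99	0	25	0	26303	0	71	0	59	16	288	409	261	128	61	322	0	5	0	3	116	7	12	131	2093	99	63	18	49	0	358	3332	42	0	237	302	355	226	10	43	0	30	395
S2016.02.15m.0.2	1011	116	7474	93	1794	595	0	53	12131	47	570	105	0	630	8	14	3	22	17	114	52	395	50	0	8	10	3	2	51	60	281	230	157	19	0	69	541	89	0	41	354	121	112	37	74	0	336	442
S2016.02.15m.3.0	202	26	9298	243	100	245	0	118	84	34	1837	85	0	53	41	5868	46	85	537	44	255	744	63	0	62	70	11	38	3621	116	262	70	364	1925	0	678	94	824	0	31	514	313	35	562	242	0	742	382
S2016.03.15m.0.2	15	6	1717	37	54	4	0	210	203	29557	77	13	0	147	8	3	804	6	0	0	211	12	1	0	0	1	7	5	96	14	3	4	9	4	0	6	15	6	0	15	20	29	10	3	0	0	2	5
S2016.03.15m.3.0	11	7	1	143	2	4	0	73	0	194	1	41	0	5	5	23917	71	9	11336	0	634	0	0	0	176	0	6	3	43	1	45	23	4	8	0	39	14	9	0	7	4	13	2	1	1	0	10	2
S2016.04.15m.0.2	1056	312	2044	333	96	88	0	32	244	3518	1895	544	0	30	258	216	163	8	60	35	213	18	8	0	13	3	24	10	195	249	320	29	501	80	0	446	99	208	0	3542	621	103	421	66	430	0	225	317
S2016.04.15m.3.0	649	28	2373	722	56	312	0	2162	234	466	498	190	0	2209	199	13	105	608	1452	299	321	29	132	0	12	564	220	436	2159	2911	1549	223	5790	174	0	997	407	513	0	1848	1017	4499	246	754	432	0	726	586
S2016.05.15m.0.2	443	53	51	78	22	110	0	668	17	15182	1087	5	0	178	66	2285	2226	926	114	36	801	71	44	0	403	147	6	6	4154	31	32	57	148	694	0	52	623	35	0	165	242	442	109	22	226	0	643	16
S2016.05.15m.3.0	441	48	41	629	9	38	0	12	46	57	729	11	0	498	109	669	26	287	2413	39	431	812	18	0	271	59	53	434	49	1821	1443	329	300	309	0	7428	2113	224	0	1461	486	107	173	279	370	0	74	129
S2016.06.15m.0.2	2	0	0	5	1	6	0	1	0	0	2	5	0	19	19	34531	2	22	2159	18	0	0	6	0	31	1	2	6	219	33	16	5	8	163	0	8	18	19	0	54	32	10	3	3	12	0	18	17
S2016.06.15m.3.0	63	81	304	468	610	843	0	78	118	128	2120	40	0	26	98	69	178	593	76	86	744	136	24	0	11	27	106	424	1524	450	4372	265	353	1674	0	2757	1063	254	0	393	926	261	2828	185	2235	0	1614	2599
S2016.07.15m.0.2	1656	3	163	23	21	33	0	16082	14	2772	219	354	0	65	750	9	2188	735	7	19	3208	629	57	0	1	110	157	477	1724	3008	64	35	104	276	0	766	158	580	0	95	79	457	50	232	351	0	160	130
S2016.07.15m.3.0	14	0	2	1	5	2	0	143	4	121	18	2	0	3	44	1169	13247	500	1058	75	5242	21	12	0	15	2	22	15	236	135	244	416	71	47	0	19	329	13	0	179	35	149	9	15	99	0	6	9
S2016.08.15m.0.2	191	142	275	76	311	41	0	2	13	5155	89	229	0	36	1251	1	6580	43	2	94	6534	67	111	0	5	30	68	143	4041	52	1099	35	94	153	0	1047	274	609	0	375	149	117	187	201	1567	0	220	194
S2016.08.15m.3.0	44	18	3	31	2	14	0	2	26	61	147	33	0	185	113	8	61	217	2	6915	1725	196	70	0	9	7	1228	250	1265	88	1991	23	181	167	0	2800	4042	186	0	200	1347	142	206	115	325	0	335	1174
S2016.09.15m.0.2	360	8	17	237	9	58	0	1166	7	78	0	464	0	42	141	2830	71	163	3517	64	46	4	369	0	571	16	267	173	1923	466	686	70	1676	163	0	222	436	400	0	71	1560	187	324	272	696	0	211	532
S2016.09.15m.3.0	29	181	2304	190	85	188	0	1628	877	5	694	67	0	759	979	2294	67	2978	131	881	46	4230	350	0	901	174	225	82	1215	1817	218	381	88	2389	0	275	1672	441	0	79	996	1455	104	723	1576	0	909	352
S2016.10.15m.0.2	122	27	122	415	2	129	0	23196	1	32	29	131	0	158	526	745	42	522	86	63	172	15	105	0	2518	294	12	123	509	48	64	29	2134	613	0	2399	349	631	0	24	342	131	137	12	121	0	134	64
S2016.10.15m.3.0	1	0	18960	0	164	1	0	6	681	0	3620	0	0	1	0	38	0	2	6	4	0	10814	0	0	17	0	1	0	15	6	0	4	2	10	0	1	10	4	0	8	1	26	0	2	5	0	9	3
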