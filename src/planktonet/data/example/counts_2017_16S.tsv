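	ASV0001	ASV0002	ASV0003	ASV0004	ASV0005	ASV0006	ASV0007	ASV0008	ASV0009	ASV0010	ASV0011	ASV0012	ASV0013	ASV0014	ASV0015	ASV0016	ASV0017	ASV0018	ASV0019	ASV0020	ASV0021	ASV0022	ASV0023	ASV0024	ASV0025	ASV0026	ASV0027	ASV0028	ASV0113	ASV0114	ASV0115	ASV0116	ASV0117	ASV0118	ASV0119	ASV0120	ASV0121	ASV0122	ASV0123	ASV0124	ASV0125	ASV0126	ASV0127	ASV0128	ASV0129	ASV0130	ASV0131	ASV_UCYNA
S2017.01.15m.0.2	61	571	38	347	96	235	0	73	161	34455	15	89	0	5	20	13	67	0	7	28	103	3	7	4	1	4	3	9	136	22	38	54	124	51	150	68	105	137	35	9	51	22	0	19	142	44	73	37
S2017.01.15m.3.0	39	8	4	70	0	118	0	175	0	9276	0	85	0	170	133	176	2565	0	35	8	1712	8	12	39	0	6	17	43	673	574	109	293	27	346	7	170	835	96	206	536	155	1509	87	400	80	78	53	124
S2017.02.15m.0.2	23	6	1	6	2	20	0	20889	1	4720	1	13	0	53	1	1	45	0	2	0	34	1	0	0	2	1	2	3	28	10	25	23	10	9	4	23	146	21	2	2	194	2	0	7	1	1	20	3
S2017.02.15m.3.0	3	1	0	4	0	28	0	34	9	0	5	6	0	8	1	25411	0	0	1545	1	1	0	0	3	1778	0	0	0	15	3	12	3	4	7	4	0	12	2	24	3	9	0	3	4	5	3	43	2
S2017.03.15m.0.2	7934	965	4788	659	640	63	0	660	420	478	145	4765	0	171	398	149	10	0	45	31	108	17	31	51	38	35	11	19	591	67	101	120	148	70	628	148	80	94	611	38	174	1055	93	436	146	41	33	1773
S2017.03.15m.3.0	5	39	39	662	0	92	0	76	21	2132	5	60	0	35	75	0	32	0	0	3	245	10	32	4	0	2	3	14	9503	222	524	17	77	566	5	105	159	268	8	27	75	203	125	5	34	38	69	73
S2017.04.15m.0.2	1111	42	8520	456	67	10	0	150	1620	280	3045	206	0	84	147	292	364	0	84	51	1580	79	3	15	1	20	32	122	85	588	97	154	84	47	308	878	224	143	89	223	207	183	233	702	294	163	88	220
S2017.04.15m.3.0	418	156	252	55	44	47	0	8362	39	2	230	328	0	67	28	207	0	0	28	21	5	65	26	8	86	5	1663	226	1430	76	420	103	89	129	510	467	286	500	366	108	461	686	270	243	17457	99	337	53
S2017.05.15m.0.2	201	75	717	3474	196	11	0	69	204	8339	8341	41	0	356	431	0	226	0	3	124	722	241	5	4	1	34	20	3	375	255	130	62	87	180	292	1830	202	242	1483	160	197	2822	48	273	51	30	13	7
S2017.05.15m.3.0	3846	30	14	396	46	33	0	1491	4	13	16	472	0	151	298	5	42	0	2	7	12	60	33	29	3	293	17	57	3408	1990	589	537	915	1176	252	758	849	1244	167	713	328	3523	420	430	738	148	330	5
S2017.06.15m.0.2	12	3	6354	58	68	37	0	54	4287	4	5966	723	0	1	133	11	4	0	5	40	158	2991	5	187	1	95	60	30	276	142	107	610	25	28	366	123	10	36	3184	16	776	305	75	26	180	637	48	102
S2017.06.15m.3.0	33	16	209	20	142	66	0	614	12	231	528	3	0	31	200	11494	96	0	1995	190	396	208	120	161	1256	1556	182	734	609	108	400	491	282	12	642	221	430	85	312	613	152	2540	145	184	262	136	945	1477
S2017.07.15m.0.2	64	13	10	33	3	22	0	11654	6	1169	3	9	0	118	94	15	249	0	24	51	9230	6	2	163	1	2	16	11	224	146	10	33	24	85	25	480	1659	100	40	33	531	59	27	27	103	173	93	130
S2017.07.15m.3.0	2	1	1468	2	4115	0	0	140	611	116	2275	3	0	1	9	513	1634	0	1521	33	131	10347	0	25	14	4	0	4	42	33	111	3	2	7	51	2	24	255	12	2	13	107	3	4	5	2	15	0
S2017.08.15m.0.2	5	11	3	43	2	184	0	19292	14	16	190	26	0	43	13	0	277	0	7	19	28	212	9	50	6	0	26	15	116	45	93	103	15	52	82	202	429	352	134	102	18	223	3	21	8	10	67	17
S2017.08.15m.3.0	107	5	4317	56	745	1	0	0	143	32	992	2	0	1	334	19363	88	0	1337	12	58	7433	119	34	499	151	8	11	341	297	95	78	36	92	49	162	27	17	477	39	72	118	32	18	591	55	16	356
S2017.09.15m.0.2	307	59	62	14	0	40	0	15	42	14831	41	67	0	231	162	71	534	0	40	82	7100	5	600	648	34	121	97	261	1516	98	44	58	38	37	326	540	81	171	481	136	287	111	113	210	116	15	227	1009
S2017.09.15m.3.0	1204	13	767	49	67	375	0	1840	696	6	38	86	0	55	791	631	20	0	298	173	245	3557	1612	731	239	24	41	152	5334	48	167	195	212	501	310	471	1638	120	346	780	455	926	359	182	67	236	1777	95
S2017.10.15m.0.2	102	38	0	2557	3	91	0	2	0	47	11	1477	0	533	4788	703	15	0	411	102	136	1	35	383	411	72	33	173	345	321	5624	22	575	1444	659	3153	1469	38	1156	110	316	370	456	543	217	303	719	177
S2017.10.15m.3.0	103	43	2006	68	186	41	0	232	1521	162	473	19	0	53	228	1	132	0	4	44	100	580	275	117	36	17	46	0	614	13	159	178	182	231	1088	1434	668	210	87	1320	17105	136	46	11	468	8	134	7
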