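	NCP	POC	PON
S2016.01.15m.0.2	6.664733181790428	4.625113452893313	0.5374602507619467
S2016.01.15m.3.0	11.334997599970057	8.157172761301734	0.7555784248590413
S2016.02.15m.0.2	27.363813681886192	3.848589137320107	0.6965006509915985
S2016.02.15m.3.0	12.325249391556005	4.826422229872992	0.4980179083958493
S2016.03.15m.0.2	9.637692624478081	5.286405619409729	0.8177168946143142
S2016.03.15m.3.0	1.6201627575673143	4.438099876310957	0.5226453523721526
S2016.04.15m.0.2	26.268588214549972	3.413917832700503	0.8735404924769121
S2016.04.15m.3.0	16.9606989515815	4.154414213966239	1.0727037198992888
S2016.05.15m.0.2	6.487362665883174	4.103120688407899	1.0339038544699122
S2016.05.15m.3.0	7.688741378781659	3.409337610835065	0.7617369780768717
S2016.06.15m.0.2	8.698206348527982	3.0564076560468285	0.4814129140815166
S2016.06.15m.3.0	25.85317692599792	1.4497571261951534	0.7810841720202177
S2016.07.15m.0.2	18.416189951814083	7.32022895988729	0.8954366828510587
S2016.07.15m.3.0	-5.21292575563195	5.456568131728407	0.6914642964085804
S2016.08.15m.0.2	-1.8429578921516292	3.512423130764091	0.8378974549397239
S2016.08.15m.3.0	17.302352414145357	3.516380470647285	0.9710664878904486
S2016.09.15m.0.2	11.254684793794679	4.480097261313857	1.02165934595557
S2016.09.15m.3.0	18.35885887680968	4.279493851378092	0.9250547941826512
S2016.10.15m.0.2	21.308155010124715	5.244383534339129	1.0004954512520747
S2016.10.15m.3.0	19.87180318181558	4.665995510559792	0.7368313830611299
S2017.01.15m.0.2	5.032177187909287	3.698437451286451	0.9725611983230845
S2017.01.15m.3.0	-6.499766605784487	3.9218126071020025	0.6689330486507841
S2017.02.15m.0.2	11.716111961770666	6.53103061849582	0.9282867674969745
S2017.02.15m.3.0	5.545993153394831	5.268727382436897	0.46345862559434825
S2017.03.15m.0.2	18.680671695027918	4.843772141530828	0.595739211920044
S2017.03.15m.3.0	14.840260285636665	6.011092304092526	0.8090913908482571
S2017.04.15m.0.2	11.821126488697395	4.127491418204353	0.9111231466165719
S2017.04.15m.3.0	20.65041927538025	6.5921701823173	0.964110390161155
S2017.05.15m.0.2	10.404071690537428	4.581795419454119	0.9971700238342583
S2017.05.15m.3.0	14.306478113166428	5.062139041978045	1.0657417933016542
S2017.06.15m.0.2	4.364098165154867	3.1911988325342753	0.9108014393291994
S2017.06.15m.3.0	9.727382270493392	4.350224451602466	0.8030670093902964
S2017.07.15m.0.2	0.5148572928892783	5.944833889726254	0.9712733957239941
S2017.07.15m.3.0	11.41606882665065	5.490868664410617	0.511807326504599
S2017.08.15m.0.2	-7.226971811440016	6.497328373170305	0.960154318388811
S2017.08.15m.3.0	15.867653960414973	5.425359115891216	0.8299662288270641
S2017.09.15m.0.2	4.556971207731442	5.105273926598354	0.8069867132784823
S2017.09.15m.3.0	7.881349910685957	5.6761271901864925	0.9399259042477628
S2017.10.15m.0.2	11.97401990358717	4.578900617518524	0.8371595387489084
S2017.10.15m.3.0	1.4687193794766138	6.493856078253835	1.127685673416134
S2019.01.15m.0.2	5.885784874416542	4.1058012642927295	0.7565015131856538
S2019.01.15m.3.0	17.7844569690062	6.042842019067489	0.733320026603476
S2019.02.15m.0.2	26.438952617475948	3.8026009641171297	1.0319304572261538
S2019.02.15m.3.0	15.401512018963906	4.107166587299273	1.0186840442481027
S2019.03.15m.0.2	16.839833506757117	6.747144113830147	0.8390135814406073
S2019.03.15m.3.0	-3.1983859337342953	4.847387566362734	0.8148934242087926
S2019.04.15m.0.2	14.65101460050384	6.616648341030695	0.9857321033046317
S2019.04.15m.3.0	13.837030824780058	3.7960206481605776	0.6800703262556108
S2019.05.15m.0.2	3.871483588679393	4.8995912436749745	0.6681059023643795
S2019.05.15m.3.0	9.914719384883753	6.05152861737849	0.6598102589783422
S2019.06.15m.0.2	11.77569562548353	5.076300101953078	0.6267080933583651
S2019.06.15m.3.0	4.429423588620568	6.048870361409766	0.920620647954022
S2019.07.15m.0.2	9.866349242400538	5.615274361584045	0.9161404082650445
S2019.07.15m.3.0	25.125134728858168	6.240507250310373	0.7042258319522609
S2019.08.15m.0.2	6.732848705293714	3.849751526449161	0.7294082687378179
S2019.08.15m.3.0	11.19833083719473	4.91241722820917	0.6209425449254504
S2019.09.15m.0.2	12.211177816197969	3.8153013807249243	0.7544973564321372
S2019.09.15m.3.0	9.169552683301635	5.136206994576341	0.6903025384996017
S2019.10.15m.0.2	2.8564038956308195	6.315894380019737	0.9778135454699223
S2019.10.15m.3.0	10.317073927855716	5.422059961622292	0.865202411132486
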