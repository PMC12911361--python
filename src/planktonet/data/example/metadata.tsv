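sample_id	year	month	latitude	depth	depth_bin	size_fraction	salinity	chlorophyll	region
S2016.01.15m.0.2	2016	June	22.0	15.0	0-15	0.2	35.36153752232862	0.05261475655638708	NPSG
S2016.01.15m.3.0	2016	June	22.0	15.0	0-15	3.0	35.32563625363415	0.043815802435502475	NPSG
S2016.02.15m.0.2	2016	June	24.22222222222222	15.0	0-15	0.2	35.241832539431165	0.054392765144866226	NPSG
S2016.02.15m.3.0	2016	June	24.22222222222222	15.0	0-15	3.0	35.19121222149006	0.04942923066040876	NPSG
S2016.03.15m.0.2	2016	June	26.444444444444443	15.0	0-15	0.2	35.14406178571371	0.04920390453047732	NPSG
S2016.03.15m.3.0	2016	June	26.444444444444443	15.0	0-15	3.0	35.14986824896184	0.05266297793387506	NPSG
S2016.04.15m.0.2	2016	June	28.666666666666668	15.0	0-15	0.2	34.97927095010518	0.046925908409822414	NPSG
S2016.04.15m.3.0	2016	June	28.666666666666668	15.0	0-15	3.0	35.022286125793144	0.052547790194798785	NPSG
S2016.05.15m.0.2	2016	June	30.88888888888889	15.0	0-15	0.2	34.9209740483992	0.05085025366126433	NPSG
S2016.05.15m.3.0	2016	June	30.88888888888889	15.0	0-15	3.0	34.88670007349887	0.06475017480449197	NPSG
S2016.06.15m.0.2	2016	June	33.111111111111114	15.0	0-15	0.2	34.78352758059027	0.08618192101090566	STZ
S2016.06.15m.3.0	2016	June	33.111111111111114	15.0	0-15	3.0	34.78069434427783	0.09885593762859657	STZ
S2016.07.15m.0.2	2016	June	35.333333333333336	15.0	0-15	0.2	34.60715455323587	0.27293147879531393	NTZ
S2016.07.15m.3.0	2016	June	35.333333333333336	15.0	0-15	3.0	34.677766882425765	0.3055338191258378	NTZ
S2016.08.15m.0.2	2016	June	37.55555555555556	15.0	0-15	0.2	34.54293863541219	0.34891385556718213	NTZ
S2016.08.15m.3.0	2016	June	37.55555555555556	15.0	0-15	3.0	34.51089643661525	0.3538971319756082	NTZ
S2016.09.15m.0.2	2016	June	39.77777777777778	15.0	0-15	0.2	34.43698245952723	0.28373658976873056	NTZ
S2016.09.15m.3.0	2016	June	39.77777777777778	15.0	0-15	3.0	34.442155486870675	0.3440060647535146	NTZ
S2016.10.15m.0.2	2016	June	42.0	15.0	0-15	0.2	34.292524543053645	0.3640033454159096	NTZ
S2016.10.15m.3.0	2016	June	42.0	15.0	0-15	3.0	34.3735732836906	0.33862480889890817	NTZ
S2017.01.15m.0.2	2017	June	22.0	15.0	0-15	0.2	35.361819319350396	0.048036523865254005	NPSG
S2017.01.15m.3.0	2017	June	22.0	15.0	0-15	3.0	35.31293085657516	0.05273188023063669	NPSG
S2017.02.15m.0.2	2017	June	24.22222222222222	15.0	0-15	0.2	35.275101017427666	0.0514423823850732	NPSG
S2017.02.15m.3.0	2017	June	24.22222222222222	15.0	0-15	3.0	35.20555050632649	0.046528856837551424	NPSG
S2017.03.15m.0.2	2017	June	26.444444444444443	15.0	0-15	0.2	35.117203974914695	0.049321775931406193	NPSG
S2017.03.15m.3.0	2017	June	26.444444444444443	15.0	0-15	3.0	35.09129969177085	0.054422944052198	NPSG
S2017.04.15m.0.2	2017	June	28.666666666666668	15.0	0-15	0.2	34.990660921833644	0.05407483864830774	NPSG
S2017.04.15m.3.0	2017	June	28.666666666666668	15.0	0-15	3.0	34.96033657501326	0.051296567537518975	NPSG
S2017.05.15m.0.2	2017	June	30.88888888888889	15.0	0-15	0.2	34.868915305129114	0.05372037838702742	NPSG
S2017.05.15m.3.0	2017	June	30.88888888888889	15.0	0-15	3.0	34.902105153024216	0.059639391651551375	NPSG
S2017.06.15m.0.2	2017	June	33.111111111111114	15.0	0-15	0.2	34.7800555546659	0.10049399447893191	STZ
S2017.06.15m.3.0	2017	June	33.111111111111114	15.0	0-15	3.0	34.77305006037361	0.09566762444724813	STZ
S2017.07.15m.0.2	2017	June	35.333333333333336	15.0	0-15	0.2	34.692028109180356	0.2932660183880376	NTZ
S2017.07.15m.3.0	2017	June	35.333333333333336	15.0	0-15	3.0	34.61869990569476	0.2600019859030493	NTZ
S2017.08.15m.0.2	2017	June	37.55555555555556	15.0	0-15	0.2	34.56495583955734	0.31496282243342527	NTZ
S2017.08.15m.3.0	2017	June	37.55555555555556	15.0	0-15	3.0	34.539851201083756	0.29724103675560515	NTZ
S2017.09.15m.0.2	2017	June	39.77777777777778	15.0	0-15	0.2	34.42175700313464	0.2903118709819945	NTZ
S2017.09.15m.3.0	2017	June	39.77777777777778	15.0	0-15	3.0	34.460328330025526	0.33688528972667536	NTZ
S2017.10.15m.0.2	2017	June	42.0	15.0	0-15	0.2	34.335102133688046	0.3467300514805576	NTZ
S2017.10.15m.3.0	2017	June	42.0	15.0	0-15	3.0	34.33376415947082	0.3269513130667626	NTZ
S2019.01.15m.0.2	2019	May	22.0	15.0	0-15	0.2	35.31273025569763	0.0514755385143682	NPSG
S2019.01.15m.3.0	2019	May	22.0	15.0	0-15	3.0	35.31763390863593	0.04857881248992579	NPSG
S2019.02.15m.0.2	2019	May	24.22222222222222	15.0	0-15	0.2	35.21609897320478	0.05541618095048604	NPSG
S2019.02.15m.3.0	2019	May	24.22222222222222	15.0	0-15	3.0	35.22092210193026	0.049165462163057026	NPSG
S2019.03.15m.0.2	2019	May	26.444444444444443	15.0	0-15	0.2	35.08707483687555	0.04474661693039962	NPSG
S2019.03.15m.3.0	2019	May	26.444444444444443	15.0	0-15	3.0	35.086721033707875	0.04800026896958233	NPSG
S2019.04.15m.0.2	2019	May	28.666666666666668	15.0	0-15	0.2	35.00663161567151	0.051458256119227046	NPSG
S2019.04.15m.3.0	2019	May	28.666666666666668	15.0	0-15	3.0	34.98724347382607	0.04478299009022972	NPSG
S2019.05.15m.0.2	2019	May	30.88888888888889	15.0	0-15	0.2	34.90852785178672	0.05220836135386976	NPSG
S2019.05.15m.3.0	2019	May	30.88888888888889	15.0	0-15	3.0	34.863193305875356	0.05231137432689908	NPSG
S2019.06.15m.0.2	2019	May	33.111111111111114	15.0	0-15	0.2	34.77426715597964	0.09812414179169955	STZ
S2019.06.15m.3.0	2019	May	33.111111111111114	15.0	0-15	3.0	34.76913467476841	0.08917997219699651	STZ
S2019.07.15m.0.2	2019	May	35.333333333333336	15.0	0-15	0.2	34.68571718028359	0.20183328541063278	NTZ
S2019.07.15m.3.0	2019	May	35.333333333333336	15.0	0-15	3.0	34.68891903195224	0.23549795773928733	NTZ
S2019.08.15m.0.2	2019	May	37.55555555555556	15.0	0-15	0.2	34.555798834857804	0.29598374650502085	NTZ
S2019.08.15m.3.0	2019	May	37.55555555555556	15.0	0-15	3.0	34.5298651210049	0.2500539090474774	NTZ
S2019.09.15m.0.2	2019	May	39.77777777777778	15.0	0-15	0.2	34.435568199742114	0.2819869888034512	NTZ
S2019.09.15m.3.0	2019	May	39.77777777777778	15.0	0-15	3.0	34.44227687117829	0.3246058214987904	NTZ
S2019.10.15m.0.2	2019	May	42.0	15.0	0-15	0.2	34.322261571574515	0.24907726139417394	NTZ
S2019.10.15m.3.0	2019	May	42.0	15.0	0-15	3.0	34.307664177184044	0.3480076279775995	NTZ
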