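lg	f_unique_positions	f_length_cM	f_marker_interval	m_unique_positions	m_length_cM	m_marker_interval	fm_ratio
1	880	150.398	0.17	764	96.932	0.13	1.55
2	914	128.927	0.14	576	80.311	0.14	1.61
3	1,005	167.41	0.17	797	107.838	0.14	1.55
4	798	133.264	0.17	608	94.902	0.16	1.4
5	797	107.165	0.13	564	76.823	0.14	1.39
6	1,020	147.84	0.14	1,088	154.592	0.14	0.96
7	593	98.666	0.17	515	69.364	0.13	1.42
8	951	139.04	0.15	642	89.167	0.14	1.56
9	1,006	150.924	0.15	754	97.856	0.13	1.54
10	643	94.239	0.15	498	72.248	0.15	1.3
11	1,012	145.177	0.14	883	127.862	0.14	1.14
12	718	97.291	0.14	640	72.927	0.11	1.33
13	975	123.13	0.13	663	95.595	0.14	1.29
14	690	102.484	0.15	517	72.634	0.14	1.41
15	754	112.926	0.15	607	73.845	0.12	1.53
16	939	154.868	0.16	639	101.333	0.16	1.53
17	924	134.912	0.15	760	96.545	0.13	1.4
18	1,030	152.931	0.15	610	74.318	0.12	2.06
19	814	103.42	0.13	552	75.193	0.14	1.38
20	773	134.035	0.17	592	84.287	0.14	1.59
21	753	94.889	0.13	612	89.754	0.15	1.06
22	700	128.097	0.18	502	87.469	0.17	1.46
23	808	126.172	0.16	578	75.567	0.13	1.67
24	632	104.576	0.17	462	72.957	0.16	1.43
25	693	113.383	0.16	662	89.252	0.13	1.27
26	637	104.682	0.16	504	78.919	0.16	1.33
27	777	108.956	0.14	528	68.471	0.13	1.59
28	755	112.341	0.15	697	98.77	0.14	1.14
29	619	110.117	0.18	525	69.86	0.13	1.58
Total	23,610	3,582.26	0.15	18,339	2,545.591	0.14	1.41
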