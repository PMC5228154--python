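lg	chromosome	mapped_markers	unique_positions	length_cM	marker_interval
1	1	13,426	1,198	122.48	0.1
2	20	6,626	1,031	97.624	0.09
3	2	12,838	1,340	136.613	0.1
4	4	7,754	1,090	111.502	0.1
5	13	9,869	1,017	91.712	0.09
6	3	11,507	1,312	126.625	0.1
7	11	8,000	832	83.681	0.1
8	7	10,999	1,216	112.518	0.09
9	8	8,516	1,267	122.109	0.1
10	26	6,138	850	80.721	0.09
11	5	9,256	1,364	135.765	0.1
12	12	8,264	1,010	84.4	0.08
13	18	9,330	1,286	109.138	0.08
14	28	6,728	899	86.76	0.1
15	15	7,672	999	92.755	0.09
16	9	9,293	1,180	126.838	0.11
17	6	10,052	1,286	114.924	0.09
18	14	13,475	1,226	113.228	0.09
19	23	7,429	1,038	89.178	0.09
20	10	10,797	1,050	110.144	0.1
21	21	10,074	1,021	91.477	0.09
22	17	5,628	771	103.989	0.13
23	19	10,492	995	98.423	0.1
24	24	5,361	778	88.577	0.11
25	16	7,873	994	101.438	0.1
26	22	7,161	863	91.43	0.11
27	27	7,907	864	86.565	0.1
28	25	6,084	1,068	104.627	0.1
29	29	4,538	746	89.494	0.12
Total	-	253,087	30,591	3,004.735	0.1
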