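gene_id	A1	A2	A3	A4	A5	A6	B1	B2	B3	B4	B5	B6	NT1	NT2	NT3	NT4
G01	144	152	41	26	69	69	1279	1551	964	715	799	1298	385	131	230	181
G02	954	1005	768	383	470	447	12961	10693	21233	8832	9613	4194	2866	2046	2864	3781
G03	400	408	356	303	468	270	3255	4734	7018	5803	2364	6436	2046	1134	1488	1031
G04	2678	2931	2521	981	2497	1344	16694	24078	24717	20066	17752	26180	9574	2835	7910	10039
G05	260	276	181	322	254	248	2638	2420	2314	2490	2596	4687	854	713	570	969
G06	1942	3463	1743	637	1908	2726	13131	20226	20012	27484	17251	22211	11393	6052	11771	4644
G07	261	179	116	147	254	269	1116	1300	3292	2499	1466	3216	895	420	734	1243
G08	116	72	103	54	58	97	952	987	1150	1310	767	770	307	212	235	311
G09	1846	2073	1622	655	1855	1438	16500	27756	12962	11518	11930	13457	5417	3413	2850	4251
G10	37	38	22	18	23	15	215	540	206	263	165	262	144	53	142	106
G11	1597	1340	627	979	821	958	435	866	334	940	806	1022	949	1347	909	1850
G12	1579	1811	1379	1584	1139	738	885	1246	955	768	629	1515	1350	1200	1232	1176
G13	377	414	183	186	306	396	343	272	202	119	244	398	375	366	368	188
G14	26	37	9	23	30	30	6	20	26	27	10	8	27	28	16	26
G15	1910	1261	1067	646	1551	2287	1182	1346	911	2197	731	1260	1923	816	1617	1332
G16	2173	1260	2293	2182	3466	3023	2236	957	1904	1627	826	2137	2959	2131	1275	1777
G17	286	142	171	211	285	130	79	384	154	91	145	291	75	87	141	130
G18	778	763	360	298	646	503	267	514	405	313	267	396	639	262	502	232
G19	1508	1289	983	1778	1913	2751	1272	1416	1210	629	893	834	2275	623	1769	1315
G20	495	462	261	173	371	284	187	426	80	391	220	285	214	224	233	147
G21	254	143	107	53	227	209	88	71	66	63	81	137	172	49	88	144
G22	399	681	436	354	433	501	231	452	361	367	590	780	522	367	519	557
G23	1905	1534	898	586	2177	1862	655	1692	847	873	747	1037	1317	828	1057	1604
G24	20	20	16	12	27	46	12	27	17	26	12	10	40	19	27	6
G25	1224	2395	1724	1994	2735	2256	1467	1356	1927	1901	1455	1596	2185	756	1576	1525
G26	372	145	347	175	269	389	218	254	192	251	113	152	296	187	152	134
G27	547	732	293	523	1050	573	426	742	364	340	338	515	1353	325	418	801
G28	590	628	284	382	291	1012	238	629	210	529	285	573	377	327	327	584
G29	31	39	60	41	71	73	46	30	34	42	32	46	56	19	26	29
G30	292	186	206	132	202	219	97	235	120	177	82	98	205	88	66	156
G31	66	58	22	27	77	83	48	45	64	26	31	79	56	25	56	67
G32	1947	2247	2179	1522	1387	2297	1327	2071	1667	635	1164	1835	3181	1131	1769	3156
G33	1395	1077	586	294	1259	572	543	379	629	407	506	368	1042	615	741	579
G34	42	39	32	35	34	64	30	66	30	44	24	30	42	15	28	23
G35	42	19	20	55	20	48	25	17	28	46	33	30	39	19	34	33
G36	87	27	74	33	72	70	44	42	54	12	52	66	35	30	49	83
G37	78	36	44	54	30	52	40	39	30	70	44	86	31	39	25	77
G38	1768	1902	1183	1569	806	1298	798	1195	489	1282	359	1181	1026	889	439	840
G39	67	23	42	46	36	29	13	22	23	19	32	38	35	10	31	45
G40	29	35	20	9	64	67	10	44	20	21	10	14	35	11	9	35
G41	14	34	26	27	38	32	27	29	6	28	17	28	20	14	26	32
G42	126	222	247	100	170	112	49	121	121	146	63	130	119	103	97	117
G43	802	959	810	627	1025	993	430	755	433	495	564	550	657	566	701	686
G44	58	122	160	58	76	149	68	77	47	69	51	96	101	73	48	95
G45	69	74	80	40	39	54	21	86	82	52	34	67	86	30	42	66
G46	67	74	61	94	152	140	54	183	54	51	57	75	88	45	162	107
G47	230	283	117	124	336	171	95	145	157	62	111	133	148	92	159	185
G48	26	57	34	21	36	20	20	24	34	35	8	36	25	23	37	30
G49	46	100	45	24	41	39	21	59	26	28	35	41	52	21	21	44
G50	110	230	90	111	196	181	92	134	118	172	209	142	262	132	126	154
G51	634	640	525	476	599	425	314	431	723	533	755	727	676	491	395	716
G52	66	39	13	27	38	12	16	20	25	30	24	23	34	25	11	24
G53	118	85	86	90	70	93	63	133	51	74	33	59	117	35	61	181
G54	985	1508	1366	658	1484	1905	1180	2469	902	1067	928	901	1269	1510	1516	1520
G55	541	685	537	444	1119	619	599	1130	428	482	350	914	937	358	703	1078
G56	2378	1720	1992	1987	1196	2381	1264	1445	1015	689	855	1103	2523	733	1256	1488
G57	380	274	275	266	262	412	251	523	274	405	275	297	312	306	344	444
G58	9	27	38	19	48	27	14	35	19	19	42	19	35	32	15	18
G59	54	80	45	33	36	15	20	55	30	25	24	42	19	15	40	56
G60	27	44	38	32	17	41	22	46	42	9	16	30	37	24	36	40
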