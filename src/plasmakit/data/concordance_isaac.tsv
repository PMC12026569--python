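sample_id	category	total	common	uncommon	pct_common_printed	mean_cov_uncommon
1	father_inherited	3448	1633	1815	47	3.8
1	de_novo	6754	2446	4308	36	2.2
2	father_inherited	559	487	72	87	10.6
2	de_novo	309	309	0	100	19.3
3	father_inherited	460	444	16	96	5.6
3	de_novo	272	272	0	100	15.8
4	father_inherited	2682	1583	1099	59	4.0
4	de_novo	4038	1613	2425	40	1.6
5	father_inherited	3652	1920	1732	52	4.2
5	de_novo	6139	2018	4121	33	1.6
6	father_inherited	2700	1256	1444	46	3.2
6	de_novo	4656	1587	3069	34	1.7
7	father_inherited	1921	1379	542	72	3.1
7	de_novo	1838	1118	720	61	1.4
8	father_inherited	530	525	5	99	11.5
8	de_novo	343	341	2	99	7.0
9	father_inherited	448	438	10	98	15.0
9	de_novo	320	320	0	100	12.8
10	father_inherited	164	89	75	54	3.0
10	de_novo	680	476	204	70	3.3
11	father_inherited	500	483	17	96	5.7
11	de_novo	204	204	0	100	8.8
12	father_inherited	468	465	3	99	8.4
12	de_novo	301	258	43	86	6.9
13	father_inherited	464	402	62	87	5.6
13	de_novo	288	288	0	100	4.5
14	father_inherited	2720	1605	1115	59	3.5
14	de_novo	4383	1535	2848	35	1.4
15	father_inherited	426	233	193	55	1.5
15	de_novo	1832	231	1601	13	0.9
16	father_inherited	458	441	17	96	15.4
16	de_novo	405	287	118	71	3.3
17	father_inherited	498	491	7	99	9.2
17	de_novo	290	290	0	100	7.2
18	father_inherited	478	478	0	100	21.0
18	de_novo	304	304	0	100	3.7
19	father_inherited	490	488	2	99	18.4
19	de_novo	258	258	0	100	24.4
20	father_inherited	410	336	74	82	5.7
20	de_novo	3222	262	2960	8	0.8
21	father_inherited	470	271	199	56	2.2
21	de_novo	221	147	74	67	2.5
22	father_inherited	6586	1958	4628	30	3.5
22	de_novo	3214	2112	1102	66	1.5
23	father_inherited	478	249	229	52	2.7
23	de_novo	315	240	75	76	3.7
24	father_inherited	1952	1511	441	77	5.2
24	de_novo	1952	1511	441	77	1.9
25	father_inherited	481	453	28	94	12.3
25	de_novo	318	318	0	100	9.9
26	father_inherited	610	535	75	88	9.8
26	de_novo	355	350	5	99	17.1
27	father_inherited	2900	1700	1200	59	3.9
27	de_novo	5000	1800	3200	36	2.0
28	father_inherited	430	380	50	88	6.5
28	de_novo	260	255	5	98	5.2
29	father_inherited	580	565	15	97	13.5
29	de_novo	330	330	0	100	11.0
30	father_inherited	2500	1150	1350	46	3.0
30	de_novo	4500	1500	3000	33	1.8
31	father_inherited	1800	1300	500	72	3.3
31	de_novo	1700	1050	650	62	1.3
32	father_inherited	495	490	5	99	10.0
32	de_novo	310	308	2	99	6.8
33	father_inherited	450	440	10	98	16.0
33	de_novo	300	300	0	100	13.0
34	father_inherited	150	80	70	53	3.1
34	de_novo	700	490	210	70	3.5
35	father_inherited	510	490	20	96	7.5
35	de_novo	210	210	0	100	9.0
36	father_inherited	470	460	10	98	10.0
36	de_novo	295	250	45	85	7.1
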