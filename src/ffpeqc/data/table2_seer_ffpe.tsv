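sample_id	input_for_libprep	rin	dv200	dv100	dv50	lib_size	lib_yield	lib_molarity	storage_time	resequenced	contamination_pct	cluster_label	genes_detected
SEER_020	672.3	2.3	30	75	98	413	34.8	10.3	7	N	22.61	B	14216
SEER_064	1000	2.3	42	73	90	478	78	18.6	7	Y	55.47	C	13844
SEER_041	1000	2.5	11	41	98	428	8.28	2.4	9	N	4.69	D	4541
SEER_042	1000	2.2	39	81	99	334	5467.95	190	9	Y	0.38	B	4850
SEER_043	1000	2.4	14	50	97	421	19.8	5.9	9	N	13.31	D	6429
SEER_044	232.4	2.7	NA	NA	NA	393	7.26	2.5	9	N	4.25	D	16093
SEER_045	1000	2.4	16	55	98	368	12.5	4.6	9	Y	9.08	D	14766
SEER_065	1000	2.3	21	64	98	456	3.14	0.84	9	Y	23.83	D	60
SEER_060	747	2.6	6	30	94	445	4.55	1.2	10	N	24.75	B	27053
SEER_061	1000	2.2	50	86	100	331	246	91	10	Y	0.48	B	5169
SEER_016	597.8	2.5	17	60	98	375	985.95	363.2	12	N	39.06		15313
SEER_017	1000	1	NA	NA	NA	365	3.69	1.15	12	N	2.04	D	24435
SEER_019	1000	2.4	21	64	98	393	207.9	66	12	N	12.3	B	22417
SEER_021	1000	2.4	18	67	99	337	417.45	154.9	12	N	1.22	B	9993
SEER_052	391.05	2.4	11	43	96	405	8.55	2.6	12	N	3.95	D	15398
SEER_013	1000	2.1	35	81	99	312	286.8	105	13	Y	0.51	B	17729
SEER_014	568	2.5	17	66	99	355	10.47	3.33	13	N	3.16	B	21893
SEER_015	1024	2.4	13	56	98	364	456.75	159.4	13	N	31.93		5688
SEER_018	1000	2.1	36	82	100	290	216.9	83	13	Y	0.08	C	21580
SEER_022	1000	2.6	4	42	98	372	197.55	43.4	13	N	2.06	C	20620
SEER_023	1000	2.4	5	34	97	371	389.1	145.1	13	N	33.26		22385
SEER_051	1000	2.4	15	56	98	405	9.77	3	13	N	8.39	D	9062
SEER_012	907.5	NA	10	65	99	329	28.13	9.46	14	Y	1.22	B	18627
SEER_050	1000	2.4	13	59	98	376	21	6.6	14	Y	7.22	D	16584
SEER_066	1000	2.4	12	56	99	426	86.1	26	14	N	21.89	D	17
SEER_029	237.6	2.5	12	35	93	426	24.45	7	15	Y	27.38	D	31105
SEER_049	2000	1.7	NA	NA	NA	446	6.56	1.5	15	N	7.09	D	3380
SEER_010	1000	1.1	NA	NA	NA	315	44.21	15.23	16	Y	0.58	B	17485
SEER_011	682.5	2.2	NA	NA	NA	411	1.11	0.3	16	N	3.76		22
SEER_027	830.7	2.5	9	51	98	385	84.75	27.7	16	N	9.36	B	9056
SEER_009	369.75	NA	NA	NA	NA	353	8.58	2.65	17	Y	5.11	B	17832
SEER_048	1000	2.4	15	55	97	399	13.62	4.2	17	N	10.27	C	5981
SEER_007	1000	1	NA	NA	NA	408	5.04	1.43	18	Y	1.71	C	42
SEER_008	4731	1.1	NA	NA	NA	307	211.35	82.7	18	Y	0.08	D	8177
SEER_025	576.2	2.5	11	50	97	408	50.25	14.7	18	N	24.04	B	20527
SEER_026	1000	2.5	8	48	97	409	59.7	17.6	18	N	22.36	B	8392
SEER_046	1000	2.4	12	48	98	404	17.4	5.4	18	Y	9.89	D	4703
SEER_047	1000	2.3	22	67	99	387	23.25	7.3	18	N	10.9	D	5145
SEER_063	1000	2.3	27	77	99	356	124.2	41	18	N	0.49	B	10920
SEER_006	392.2	NA	NA	NA	NA	450	2.49	0.622	19	Y	12.02	B	12652
SEER_024	926.55	2.5	12	57	99	360	207.75	67.9	20	N	1.04	C	22926
SEER_028	697.2	2.5	9	46	96	433	38.4	10.9	20	N	23.14	B	10202
SEER_036	336.7	2.8	18	59	98	410	8.79	2.7	21	N	9.18	D	4115
SEER_057	1000	2.2	26	68	98	571	5.81	1.4	21	N	24.29	D	14391
SEER_058	1000	2.4	12	51	97	479	4.89	1.3	21	Y	29.53	D	27840
SEER_059	1000	2.4	12	53	97	520	8.3	2	21	N	18.6	C	23689
SEER_067	1000	2.3	24	71	99	462	84.9	24	21	N	40.39	C	24
SEER_034	1000	2.2	47	85	98	352	49.05	16	22	N	5	C	9
SEER_035	716.8	2.3	33	79	89	294	218.25	76.6	22	N	1.99	B	4000
SEER_056	21.6	NA	4	24	92	444	28.2	7.3	22	N	35.6	B	8966
SEER_037	356.25	2.6	10	47	95	406	6.63	2.04	23	N	4.38	D	8645
SEER_038	1000	2.5	13	55	97	448	6.68	1.9	23	N	8.5	D	12
SEER_039	1000	2.5	14	57	98	408	11.75	3.6	23	N	5.36	D	16370
SEER_040	93.6	1.5	7	38	76	479	15.9	4	23	Y	24.54	D	9782
SEER_055	94.6	2.3	1	11	85	450	30	7.6	23	N	35.71	B	2448
SEER_005	1000	1.1	NA	NA	NA	382	5.07	1.53	24	Y	2.69	C	8963
SEER_053	315.25	2.6	9	36	89	547	11.3	2.5	24	N	18.53	C	14759
SEER_054	1000	2.5	7	46	93	548	8.33	1.8	24	Y	41.29	B	4020
SEER_062	1000	2.3	22	74	99	344	366	126	24	N	0.41	B	4152
SEER_004	1000	2.6	NA	NA	NA	427	4.22	1.13	25	N	8.43	D	25
SEER_030	413.4	2.5	16	54	97	433	27.3	7.7	25	Y	30.66	D	10431
SEER_031	537.95	2.5	11	51	97	428	36.45	10.3	25	N	44.1	C	13883
SEER_032	256.5	2.5	13	49	96	377	84.3	26.9	25	N	6.66	C	28255
SEER_003	1000	1.1	NA	NA	NA	381	4.77	1.44	27	N	1.95	D	24
SEER_002	799.5	2.1	NA	NA	NA	402	3.2	0.882	29	N	6.47	D	17
SEER_001	696.8	NA	NA	NA	NA	424	3.8	0.983	31	Y	5.31	B	60
SEER_033	440.7	NA	21	63	98	417	67.35	19.6	no info	Y	39.79	D	3210
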