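ranking	medication	frequency	ror	ror_low	ror_high	prr
1	Entresto	1189	2.74	2.58	2.91	2.73
2	Opsumit	854	3.26	3.05	3.48	3.24
3	Repatha	538	1.27	1.17	1.38	1.27
4	Ambrisentan	495	4.40	4.06	4.77	4.36
5	Gilenya	455	1.41	1.29	1.55	1.41
6	Xolair	425	1.55	1.41	1.70	1.54
7	Remodulin	404	3.45	3.13	3.81	3.43
8	Tyvaso	371	4.59	4.14	5.09	4.55
9	Uptravi	306	2.71	2.43	3.02	2.69
10	Ofev	290	2.17	1.94	2.43	2.17
11	Veletri	273	3.68	3.29	4.11	3.65
12	Brilinta	268	7.33	6.56	8.19	7.22
13	Rinvoq	257	1.61	1.42	1.82	1.61
14	Sandostatin Lar Depot	237	1.44	1.28	1.62	1.44
15	Copaxone	230	2.57	2.27	2.90	2.56
16	Ibuprofen	217	1.32	1.17	1.49	1.32
17	Tasigna	208	2.40	2.11	2.73	2.39
18	Pomalyst	203	1.08	0.94	1.24	1.29
19	Orenitram	200	1.32	1.17	1.49	1.32
20	Ranolazine	198	14.64	12.84	16.69	14.17
21	Oxbryta	179	1.92	1.66	2.23	1.92
22	Adempas	178	3.27	2.83	3.79	3.26
23	Ramipril	178	2.86	2.50	3.27	2.84
24	Benlysta	172	1.93	1.67	2.23	1.93
25	Oxaliplatin	156	1.81	1.57	2.08	1.80
26	Paclitaxel	144	2.36	2.07	2.68	2.35
27	Tymlos	141	1.78	1.51	2.10	1.77
28	Symbicort	137	1.50	1.26	1.77	1.49
29	Ciprofloxacin	136	1.27	1.10	1.46	1.27
30	Trelegy Ellipta	135	1.50	1.26	1.77	1.49
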