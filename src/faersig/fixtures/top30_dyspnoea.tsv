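ranking	medication	frequency	ror	ror_low	ror_high	prr
1	Spiriva	1465	8.87	7.92	9.93	8.80
2	Salbutamol	1419	7.65	7.41	7.91	7.24
3	Entresto	5797	3.73	3.62	3.83	3.64
4	Opsumit	4134	4.41	4.28	4.55	4.29
5	Xolair	2458	2.52	2.42	2.62	2.49
6	Ambrisentan	2305	6.08	5.86	6.31	5.82
7	Remodulin	2081	5.04	4.82	5.27	4.87
8	Symbicort	2049	6.48	6.20	6.78	6.19
9	Tyvaso	1769	6.25	5.95	6.56	5.98
10	Ibrance	1565	1.16	1.11	1.22	1.16
11	Uptravi	1460	3.69	3.51	3.88	3.61
12	Ofev	1445	3.03	2.88	3.19	2.98
13	Trelegy Ellipta	1407	6.48	6.20	6.78	6.19
14	Breo Ellipta	1218	7.02	6.62	7.44	6.67
15	Advair Diskus	1183	6.69	6.35	7.04	6.37
16	Pomalyst	1097	1.59	1.50	1.69	1.58
17	Nucala	997	2.31	1.92	2.78	2.31
18	Anoro Ellipta	892	7.39	6.91	7.91	7.00
19	Oxaliplatin	887	3.45	2.64	4.50	3.38
20	Brilinta	880	7.00	6.58	7.44	6.65
21	Carboplatin	853	2.32	2.18	2.46	2.30
22	Copaxone	846	2.57	2.41	2.74	2.53
23	Zejula	821	1.18	1.10	1.26	1.17
24	Ibuprofen	817	1.30	1.22	1.39	1.30
25	Veletri	804	3.20	3.01	3.41	3.14
26	Orenitram	781	1.29	1.19	1.35	1.29
27	Nivolumab	757	1.19	1.12	1.26	1.19
28	Arikayce	712	5.04	4.72	5.39	4.87
29	Paclitaxel	707	3.46	3.27	3.66	3.39
30	Adempas	688	3.50	3.24	3.78	3.43
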