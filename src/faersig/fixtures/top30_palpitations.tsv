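ranking	medication	frequency	ror	ror_low	ror_high	prr
1	Tymlos	870	16.66	15.56	17.83	16.25
2	Entresto	486	1.50	1.36	1.65	1.5
3	Opsumit	478	2.62	2.40	2.86	2.61
4	Zejula	382	2.92	2.64	3.23	2.91
5	Gilenya	366	1.65	1.49	1.83	1.65
6	Ciprofloxacin	302	3.65	3.30	4.03	3.63
7	Copaxone	266	4.18	3.72	4.70	4.16
8	Veletri	257	4.87	4.33	5.47	4.84
9	Amlodipine	256	3.11	2.82	3.42	3.10
10	Synthroid	227	2.15	1.81	2.57	2.15
11	Ambrisentan	223	3.06	2.73	3.44	3.05
12	Xyrem	220	1.68	1.47	1.92	1.68
13	Remodulin	217	2.68	2.35	3.06	2.67
14	Ocrevus	215	1.17	1.03	1.34	1.17
15	Sertraline	211	3.39	3.04	3.77	3.37
16	Imbruvica	188	1.22	1.07	1.40	1.22
17	Orenitram	186	3.25	2.99	3.53	3.24
18	Uptravi	181	2.33	2.02	2.68	2.32
19	Ibuprofen	162	1.51	1.32	1.73	1.51
20	Tyvaso	148	2.64	2.24	3.10	2.63
21	Metoprolol	128	6.42	5.75	7.16	6.36
22	Levofloxacin	126	2.99	2.60	3.45	2.98
23	Clarithromycin	123	4.29	3.63	5.07	4.27
24	Emgality	120	1.90	1.73	2.09	1.90
25	Bisoprolol	108	4.55	3.95	5.25	4.52
26	Metoprolol Succinate	102	8.56	7.33	10.01	8.46
27	Northera	90	2.58	2.10	3.17	2.57
28	Ramipril	90	2.12	1.75	2.56	2.11
29	Ingrezza	86	1.42	1.15	1.75	1.42
30	Tasigna	86	1.39	1.13	1.71	1.39
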