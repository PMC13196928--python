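ranking	medication	frequency	ror	ror_low	ror_high	prr
1	Entresto	5351	5.49	5.32	5.67	5.38
2	Cosentyx	2325	1.69	1.62	1.76	1.69
3	Dupixent	1994	1.38	1.33	1.44	1.38
4	Xolair	1809	3.51	3.35	3.67	3.47
5	Revlimid	1612	1.09	1.04	1.15	1.09
6	Tyvaso	1537	10.19	9.68	10.73	9.77
7	Repatha	1271	1.55	1.46	1.63	1.54
8	Opsumit	1244	2.37	2.24	2.51	2.36
9	Paxlovid	1209	3.75	3.55	4.01	3.62
10	Ibrance	1157	1.62	1.53	1.71	1.61
11	Xeljanz	1055	1.65	1.59	1.73	1.65
12	Ocrevus	1037	1.99	1.88	2.12	1.98
13	Ofev	1037	4.02	3.78	4.27	3.96
14	Gilenya	867	1.39	1.30	1.48	1.39
15	Esbriet	804	1.35	1.29	1.41	1.35
16	Inflectra	738	1.28	1.22	1.34	1.27
17	Abatacept	572	3.72	3.52	3.94	3.67
18	Breo Ellipta	570	5.97	5.50	6.49	5.84
19	Nucala	535	4.52	4.26	4.80	4.45
20	Rituximab	534	1.23	1.16	1.29	1.23
21	Salbutamol	479	4.19	3.96	4.44	4.13
22	Trikafta	424	5.10	4.63	5.61	5
23	Advair Diskus	421	4.51	4.16	4.90	4.44
24	Zejula	416	1.11	1.01	1.23	1.11
25	Sandostatin Lar Depot	415	1.41	1.29	1.53	1.4
26	Anoro Ellipta	408	6.14	5.56	6.77	5.99
27	Ambrisentan	388	1.89	1.73	2.06	1.88
28	Rinvoq	380	1.22	1.10	1.35	1.22
29	Kisqali	359	1.76	1.60	1.95	1.76
30	Alemtuzumab	243	1.50	1.35	1.68	1.5
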