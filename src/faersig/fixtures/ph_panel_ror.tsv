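drug	event	ror	ror_low	ror_high
Ambrisentan	DYSPNOEA	6.08	5.86	6.31
Ambrisentan	COUGH	1.89	1.73	2.06
Ambrisentan	PALPITATIONS	3.06	2.73	3.44
Ambrisentan	CHEST PAIN	4.40	4.06	4.77
Bosentan	DYSPNOEA	4.11	3.88	4.35
Bosentan	COUGH	2.24	2.03	2.49
Bosentan	PALPITATIONS	2.98	2.57	3.46
Bosentan	CHEST PAIN	3.40	3.02	3.81
Macitentan	DYSPNOEA	4.40	4.26	4.54
Macitentan	COUGH	2.40	2.27	2.54
Macitentan	PALPITATIONS	2.64	2.41	2.89
Macitentan	CHEST PAIN	3.27	3.06	3.50
Adcirca	DYSPNOEA	3.76	3.49	4.05
Adcirca	COUGH	1.29	1.08	1.52
Adcirca	PALPITATIONS	2.58	2.11	3.16
Adcirca	CHEST PAIN	2.40	2.01	2.85
Sildenafil	DYSPNOEA	2.28	2.10	2.48
Sildenafil	COUGH	0.88	0.73	1.05
Sildenafil	PALPITATIONS	1.47	1.17	1.85
Sildenafil	CHEST PAIN	1.16	0.94	1.44
Epoprostenol	DYSPNOEA	3.36	2.84	3.99
Epoprostenol	COUGH	1.60	1.15	2.24
Epoprostenol	PALPITATIONS	2.72	1.77	4.18
Epoprostenol	CHEST PAIN	2.59	1.80	3.73
Iloprost	DYSPNOEA	3.49	2.96	4.10
Iloprost	COUGH	2.53	1.96	3.27
Iloprost	PALPITATIONS	1.32	0.73	2.39
Iloprost	CHEST PAIN	2.91	2.09	4.06
Orenitram	DYSPNOEA	5.30	5.15	5.46
Orenitram	COUGH	3.66	3.49	3.84
Orenitram	PALPITATIONS	3.25	2.99	3.53
Orenitram	CHEST PAIN	3.96	3.72	4.21
Remodulin	DYSPNOEA	5.04	4.82	5.27
Remodulin	COUGH	1.35	1.20	1.51
Remodulin	PALPITATIONS	2.68	2.35	3.06
Remodulin	CHEST PAIN	3.45	3.13	3.81
Tyvaso	DYSPNOEA	5.35	5.20	5.51
Tyvaso	COUGH	4.26	4.08	4.44
Tyvaso	PALPITATIONS	3.19	2.94	3.47
Tyvaso	CHEST PAIN	3.99	3.75	4.24
Uptravi	DYSPNOEA	3.69	3.51	3.88
Uptravi	COUGH	1.39	1.25	1.55
Uptravi	PALPITATIONS	2.33	2.02	2.68
Uptravi	CHEST PAIN	2.71	2.43	3.02
Adempas	DYSPNOEA	3.50	3.24	3.78
Adempas	COUGH	1.32	1.12	1.56
Adempas	PALPITATIONS	1.97	1.57	2.48
Adempas	CHEST PAIN	3.27	2.83	3.79
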