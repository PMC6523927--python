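mirna_id	count_a	count_b	tpm_a	tpm_b	log2_ratio	regulation	p_value	fdr
novel_mir1	193	869	5.12	31.31	2.612408	Up	1.81e-153	2.31e-152
novel_mir5	24	124	0.64	4.47	2.804131	Up	3.67e-25	2.05e-24
novel_mir6	0	48	0.001	1.73	10.75656	Up	1.12e-18	5.58e-18
novel_mir7	227	1120	6.02	40.35	2.744733	Up	1.78e-208	2.63e-207
novel_mir9	0	82	0.001	2.95	11.5265	Up	2.42e-31	1.47e-30
novel_mir10	14	894	0.37	32.21	6.44384	Up	8.00e-307	1.47e-305
novel_mir13	33	115	0.88	4.14	2.234055	Up	2.47e-18	1.21e-17
novel_mir16	17	597	0.45	21.51	5.578939	Up	1.75e-194	2.51e-193
novel_mir17	491	794	13.03	28.61	1.134682	Up	2.99e-44	2.03e-43
novel_mir19	39	81	1.03	2.92	1.503324	Up	3.24e-08	1.14e-7
novel_mir22	11	32	0.29	1.15	1.987509	Up	2.35e-05	7.14e-5
novel_mir29	82	180	2.18	6.49	1.57389	Up	9.97e-18	4.82e-17
novel_mir37	492	817	13.06	29.43	1.172133	Up	6.79e-48	4.77e-47
novel_mir38	6941	74963	184.18	2700.76	3.874177	Up	0	0
novel_mir39	164	1013	4.35	36.5	3.068809	Up	2.05e-212	3.08e-211
novel_mir40	31	86	0.82	3.1	1.918572	Up	1.06e-11	4.35e-11
novel_mir41	114	2010	3.02	72.42	4.583768	Up	0	0
novel_mir42	259	1808	6.87	65.14	3.245162	Up	0	0
novel_mir43	50	130	1.33	4.68	1.815082	Up	6.45e-16	3e-15
novel_mir45	736	2609	19.53	94	2.266969	Up	0	0
novel_mir46	143	220	3.79	7.93	1.065123	Up	3.38e-12	1.41e-11
novel_mir48	919	1754	24.39	63.19	1.373407	Up	9.10e-129	1.04e-127
novel_mir8	50	0	1.33	0.001	-10.3772	Down	1.20e-12	5.13e-12
novel_mir11	926	75	24.57	2.7	-3.18587	Down	4.68e-136	5.50e-135
novel_mir15	35	0	0.93	0.001	-9.86109	Down	4.71e-09	1.73e-8
novel_mir20	35	0	0.93	0.001	-9.86109	Down	4.71e-09	1.74e-8
novel_mir23	794	252	21.07	9.08	-1.21443	Down	3.39e-35	2.17e-34
novel_mir25	59	0	1.57	0.001	-10.6165	Down	8.33e-15	3.76e-14
novel_mir27	2970	65	78.81	2.34	-5.0738	Down	0	0
novel_mir28	16	0	0.42	0.001	-8.71425	Down	0.000168	0.000477
novel_mir33	709	173	18.81	6.23	-1.5942	Down	1.26e-46	8.65e-46
novel_mir34	479	22	12.71	0.79	-4.00797	Down	1.78e-85	1.64e-84
novel_mir36	41	0	1.09	0.001	-10.0901	Down	1.72e-10	6.84e-10
novel_mir44	34	0	0.9	0.001	-9.81378	Down	8.17e-09	2.97e-8
novel_mir53	230	47	6.1	1.69	-1.85179	Down	1.71e-19	8.64e-19
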