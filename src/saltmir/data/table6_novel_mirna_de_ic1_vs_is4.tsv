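mirna_id	count_a	count_b	tpm_a	tpm_b	log2_ratio	regulation	p_value	fdr
novel_mir6	44	256	1.87	11.62	2.6354999	Up	7.82e-41	4.42e-40
novel_mir8	338	6850	14.38	310.9	4.434315	Up	0	0
novel_mir9	0	207	0.001	9.4	13.198445	Up	5.11e-66	3.49e-65
novel_mir18	0	188	0.001	8.53	13.05833	Up	5.02e-60	3.27e-59
novel_mir19	200	1538	8.51	69.81	3.0362027	Up	3.94e-275	5.07e-274
novel_mir22	0	587	0.001	26.64	14.701306	Up	7.53e-186	7.83e-185
novel_mir30	0	200	0.001	9.08	13.148477	Up	8.25e-64	5.54e-63
novel_mir36	163	496	6.93	22.51	1.6996388	Up	5.04e-45	2.99e-44
novel_mir39	134	453	5.7	20.56	1.8508064	Up	2.78e-46	1.67e-45
novel_mir42	192	1707	8.17	77.48	3.245416	Up	0	0
novel_mir5	347	663	14.76	30.09	1.0275914	Up	2.31e-28	1.10e-27
novel_mir13	1404	298	59.72	13.53	-2.1420523	Down	2.13e-156	1.98e-155
novel_mir14	62	10	2.64	0.45	-2.552541	Down	8.44e-10	2.72e-9
novel_mir16	116	42	4.93	1.91	-1.368015	Down	2.42e-8	7.48e-8
novel_mir20	254	60	10.8	2.72	-1.9893528	Down	4.41e-27	2.07e-26
novel_mir27	10812	1387	459.9	62.95	-2.8690419	Down	0	0
novel_mir29	1387	564	59	25.6	-1.2045711	Down	1.14e-68	7.94e-68
novel_mir31	245	75	10.42	3.4	-1.6157486	Down	4.83e-20	1.98e-19
novel_mir32	4098	1680	174.31	76.25	-1.1928461	Down	3.81e-196	4.01e-195
novel_mir33	1370	157	58.27	7.13	-3.0307793	Down	2.35e-225	2.65e-224
novel_mir4	165	11	7.02	0.5	-3.811471	Down	1.52e-34	7.93e-34
novel_mir40	451	39	19.18	1.77	-3.4377815	Down	1.63e-84	1.22e-83
novel_mir44	240	0	10.21	0.001	-13.317695	Down	1.24e-69	8.68e-69
novel_mir46	759	263	32.28	11.94	-1.4348377	Down	1.01e-49	6.25e-49
novel_mir48	6461	707	274.83	32.09	-3.0983438	Down	0	0
novel_mir50	5351	1112	227.61	50.47	-2.173066	Down	0	0
novel_mir52	450	116	19.14	5.26	-1.8634561	Down	5.42e-43	3.15e-42
novel_mir53	871	180	37.05	8.17	-2.1810656	Down	6.75e-100	5.38e-99
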