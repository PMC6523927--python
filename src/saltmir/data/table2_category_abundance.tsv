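type	HC-4_count	HC-4_percent	HSA_count	HSA_percent	IC-1_count	IC-1_percent	IS-4_count	IS-4_percent
Total	47942551	100	40682196	100	43865674	100	41563472	100
Intergenic	9985569	20.83	10292988	25.3	9475423	21.6	8197558	19.72
Mature (miRNA)	3224519	6.73	1653404	4.06	6841472	15.6	5633410	13.55
Rfam other sncRNA	73325	0.15	94167	0.23	24135	0.06	35172	0.08
snRNA	1405	0	4831	0.01	2381	0.01	959	0
unmap	11040957	23.03	13725210	33.74	21005681	47.89	20270917	48.77
rRNA	1773606	3.7	1100198	2.7	244021	0.56	358242	0.86
Hairpin	38	0	9	0	80	0	147	0
snoRNA	30566	0.06	14138	0.03	9971	0.02	6058	0.01
Precursor	27019	0.06	11116	0.03	24531	0.06	40935	0.1
Repeat	21771765	45.41	13683732	33.64	6237390	14.22	7018371	16.89
tRNA	13782	0.03	102403	0.25	589	0	1703	0
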