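SeqName	Motif	Start	PWMS
lcl|NZ_AEFA01000001.1_gene_1	CUGGAA	20	2009.2156
lcl|NZ_AEFA01000001.1_gene_2	CUGGAA	414	2009.2156
lcl|NZ_AEFA01000001.1_gene_3	CUGGAA	225	2009.2156
lcl|NZ_AEFA01000001.1_gene_4	CUUGUA	31	17.9811
lcl|NZ_AEFA01000001.1_gene_5	CUGUAA	32	117.9619
lcl|NZ_AEFA01000001.1_gene_6	CUGAUG	39	7.5632
lcl|NZ_AEFA01000001.1_gene_7	CUGAUA	1	124.7508
lcl|NZ_AEFA01000001.1_gene_8	CUGGAA	438	2009.2156
lcl|NZ_AEFA01000001.1_gene_9	CUGGAA	39	2009.2156
lcl|NZ_AEFA01000001.1_gene_10	CUGAAA	471	646.2746
lcl|NZ_AEFA01000001.1_gene_11	CUGAAA	237	646.2746
lcl|NZ_AEFA01000001.1_gene_12	CUGGAA	564	2009.2159
lcl|NZ_AEFA01000001.1_gene_13	CUGAAA	213	646.2746
lcl|NZ_AEFA01000001.1_gene_14	CUGGAA	330	2009.2156
lcl|NZ_AEFA01000001.1_gene_15	CUGGAA	144	2009.2156
lcl|NZ_AEFA01000001.1_gene_16	CUGGAA	504	2009.2156
lcl|NZ_AEFA01000001.1_gene_17	CUGGAA	159	2009.2159
lcl|NZ_AEFA01000001.1_gene_18	CUGGAA	417	2009.2156
lcl|NZ_AEFA01000001.1_gene_19	CUGGAG	63	121.8117
lcl|NZ_AEFA01000001.1_gene_20	CUGGAA	606	2009.2156
lcl|NZ_AEFA01000001.1_gene_21	CUGGAA	435	2009.2156
lcl|NZ_AEFA01000001.1_gene_22	CUGGAA	63	2009.2156
lcl|NZ_AEFA01000001.1_gene_23	CUGGAA	237	2009.2156
lcl|NZ_AEFA01000001.1_gene_24	CUGGUA	671	387.8401
lcl|NZ_AEFA01000001.1_gene_25	CUGGAA	765	2009.2156
lcl|NZ_AEFA01000001.1_gene_26	CUGAAA	153	646.2746
lcl|NZ_AEFA01000001.1_gene_27	CUGGAA	387	2009.2156
lcl|NZ_AEFA01000001.1_gene_28	CUGAAA	105	646.2746
lcl|NZ_AEFA01000001.1_gene_29	CUGGAA	552	2009.2156
lcl|NZ_AEFA01000001.1_gene_30	CUGGUA	24	387.8401
lcl|NZ_AEFA01000001.1_gene_31	CUGGAA	147	2009.2156
lcl|NZ_AEFA01000001.1_gene_32	CUGGAA	348	2009.2156
lcl|NZ_AEFA01000001.1_gene_33	CUGGAA	47	2009.2156
lcl|NZ_AEFA01000001.1_gene_34	CUGGAA	354	2009.2156
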