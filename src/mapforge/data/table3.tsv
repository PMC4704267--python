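snp_id	scaffold_id	offset	wp_lg	wp_cm	ew_lg	ew_cm	scaffold_length
BARC_1.01_scaffold_1036_3469_T_C	scaffold_1036	3469	8	117.851	.	.	5173
BARC_1.01_scaffold_1448_1683_A_C	scaffold_1448	1683	17	80.252	.	.	3995
BARC_1.01_scaffold_1448_67_G_A	scaffold_1448	67	17	80.252	.	.	3995
BARC_1.01_scaffold_1454_1730_G_A	scaffold_1454	1730	1	87.464	.	.	3982
BARC_1.01_scaffold_1484_809_T_C	scaffold_1484	809	10	57.485	.	.	4368
BARC_1.01_scaffold_1605_1791_T_C	scaffold_1605	1791	9	82.196	9	80.192	3584
BARC_1.01_scaffold_169_21520_G_A	scaffold_169	21520	11	90.373	.	.	25752
BARC_1.01_scaffold_169_9083_G_T	scaffold_169	9083	11	90.373	.	.	25752
BARC_1.01_scaffold_2048_399_C_A	scaffold_2048	399	16	69.67	.	.	1779
BARC_1.01_scaffold_2182_1012_T_C	scaffold_2182	1012	13	92.688	13	134.477	1349
BARC_1.01_scaffold_22_540761_G_A	scaffold_22	540761	8	120.532	.	.	1088050
BARC_1.01_scaffold_22_985719_G_A	scaffold_22	985719	8	120.532	.	.	1088050
BARC_1.01_scaffold_2280_754_G_A	scaffold_2280	754	18	69.307	.	.	1018
BARC_1.01_scaffold_23_881897_T_C	scaffold_23	881897	1	46.789	.	.	939397
BARC_1.01_scaffold_24_197620_T_C	scaffold_24	197620	10	52.909	.	.	634454
BARC_1.01_scaffold_245_10767_A_G	scaffold_245	10767	11	87.989	.	.	17525
BARC_1.01_scaffold_248_8179_A_G	scaffold_248	8179	7	12.253	.	.	17311
BARC_1.01_scaffold_303_12268_T_G	scaffold_303	12268	3	28.82	.	.	17325
BARC_1.01_scaffold_317_4132_A_G	scaffold_317	4132	9	101.035	.	.	14271
BARC_1.01_scaffold_36_219042_G_A	scaffold_36	219042	2	75.178	2	97.615	280716
BARC_1.01_scaffold_469_2885_C_T	scaffold_469	2885	1	55.543	.	.	10200
BARC_1.01_scaffold_476_2115_T_C	scaffold_476	2115	9	57.081	9	48.989	10120
BARC_1.01_scaffold_476_9307_A_C	scaffold_476	9307	9	57.118	9	49.034	10120
BARC_1.01_scaffold_48_40550_T_C	scaffold_48	40550	9	134.091	.	.	139886
BARC_1.01_scaffold_554_3651_G_A	scaffold_554	3651	16	99.322	.	.	9124
BARC_1.01_scaffold_66_159931_A_G	scaffold_66	159931	9	60.405	9	54.911	170827
BARC_1.01_scaffold_732_107_A_G	scaffold_732	107	18	63.953	.	.	6997
BARC_1.01_scaffold_825_3928_G_T	scaffold_825	3928	2	75.353	.	.	6293
BARC_1.01_scaffold_84_64248_T_C	scaffold_84	64248	10	52.937	.	.	69299
BARC_1.01_scaffold_91_31407_G_A	scaffold_91	31407	9	58.919	9	51.365	63120
BARC_1.01_scaffold_938_1798_A_G	scaffold_938	1798	15	83.907	15	102.19	6175
BARC_1.01_scaffold_97_54858_G_A	scaffold_97	54858	9	58.919	.	.	57671
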