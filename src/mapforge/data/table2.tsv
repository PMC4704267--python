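first_marker	first_chromosome	first_position	last_marker	last_chromosome	last_position	comment	support
BARC_1.01_Gm02_22523407_T_C	Gm02	22523407	BARC_1.01_Gm02_22917212_A_G	Gm02	22917212	Move to Gm15	WP and EW
BARC_1.01_Gm02_26182810_A_G	Gm02	26182810	BARC_1.01_Gm02_27329992_A_G	Gm02	27329992	Move to Gm13	WP and EW
BARC_1.01_Gm02_43000450_C_T	Gm02	43000450	BARC_1.01_Gm02_43043202_A_C	Gm02	43043202	Re-orient	WP and EW
BARC_1.01_Gm03_5530681_A_G	Gm03	5530681	BARC_1.01_Gm03_6597027_G_A	Gm03	6597027	Re-orient	WP and EW
BARC_1.01_Gm04_29510350_C_A	Gm04	29510350	BARC_1.01_Gm04_29566738_A_G	Gm04	29566738	Re-orient and move to Gm18	WP and EW
BARC_1.01_Gm05_8031928_A_C	Gm05	8031928	BARC_1.01_Gm05_9066302_T_C	Gm05	9066302	Move to top of chromosome	WP and EW
BARC_1.01_Gm05_9616597_C_T	Gm05	9616597	BARC_1.01_Gm05_16324558_C_T	Gm05	16324558	Re-orient	WP and EW
BARC_1.01_Gm05_16504006_C_T	Gm05	16504006	BARC_1.01_Gm05_20385655_G_T	Gm05	20385655	Re-orient	WP and EW
BARC_1.01_Gm05_38634602_T_C	Gm05	38634602	BARC_1.01_Gm05_41919487_G_T	Gm05	41919487	Re-orient	WP and EW
BARC_1.01_Gm07_10457480_C_A	Gm07	10457480	BARC_1.01_Gm07_14773717_G_T	Gm07	14773717	Re-orient	WP and EW
BARC_1.01_Gm09_37436031_A_C	Gm09	37436031	BARC_1.01_Gm09_37478410_A_G	Gm09	37478410	Re-orient	WP and EW
BARC_1.01_Gm10_14435077_T_C	Gm10	14435077	BARC_1.01_Gm10_27968025_A_C	Gm10	27968025	Re-orient	WP and EW
BARC_1.01_Gm11_37808033_A_G	Gm11	37808033	BARC_1.01_Gm11_39163663_A_G	Gm11	39163663	Re-orient	WP and EW
BARC_1.01_Gm12_18007551_G_T	Gm12	18007551	BARC_1.01_Gm12_18239449_G_A	Gm12	18239449	Move to Gm04	WP and EW
BARC_1.01_Gm13_5491_A_G	Gm13	5491	BARC_1.01_Gm13_20223181_A_G	Gm13	20223181	Re-orient	WP and EW
BARC_1.01_Gm13_35242360_T_C	Gm13	35242360	BARC_1.01_Gm13_35307167_A_G	Gm13	35307167	Move to Gm09	WP and EW
BARC_1.01_Gm15_10351491_G_T	Gm15	10351491	BARC_1.01_Gm15_10427384_A_G	Gm15	10427384	Move and Re-orient	WP and EW
BARC_1.01_Gm15_36006344_T_C	Gm15	36006344	BARC_1.01_Gm15_38303424_T_C	Gm15	38303424	Move and Re-orient	WP and EW
BARC_1.01_Gm17_9749711_A_G	Gm17	9749711	BARC_1.01_Gm17_9749711_A_G	Gm17	9749711	Move to Gm10	WP and EW
BARC_1.01_Gm18_24754213_G_T	Gm18	24754213	BARC_1.01_Gm18_27432506_A_G	Gm18	27432506	Move to Gm04	WP and EW
BARC_1.01_Gm19_12811558_G_A	Gm19	12811558	BARC_1.01_Gm19_17460363_C_A	Gm19	17460363	Re-orient	WP and EW
BARC_1.01_Gm20_10352781_A_G	Gm20	10352781	BARC_1.01_Gm20_19781743_T_C	Gm20	19781743	A number of changes needed	WP and EW
BARC_1.01_Gm01_16580419_T_G	Gm01	16580419	BARC_1.01_Gm01_17671586_G_A	Gm01	17671586	Re-orient	WP
BARC_1.01_Gm02_27407299_A_G	Gm02	27407299	BARC_1.01_Gm02_29498377_C_T	Gm02	29498377	Re-orient	WP
BARC_1.01_Gm03_16199297_C_T	Gm03	16199297	BARC_1.01_Gm03_22901336_G_T	Gm03	22901336	Re-orient	WP
BARC_1.01_Gm04_34743951_T_C	Gm04	34743951	BARC_1.01_Gm04_33785067_T_C	Gm04	33785067	Move to Gm20	WP
BARC_1.01_Gm05_30871172_T_C	Gm05	30871172	BARC_1.01_Gm05_30910003_G_A	Gm05	30910003	Move to Gm11	WP
BARC_1.01_Gm08_44242727_C_T	Gm08	44242727	BARC_1.01_Gm08_44632488_A_G	Gm08	44632488	Re-orient	WP
BARC_1.01_Gm10_42894189_C_T	Gm10	42894189	BARC_1.01_Gm10_43004105_A_C	Gm10	43004105	Re-orient	WP
BARC_1.01_Gm13_34645498_A_G	Gm13	34645498	BARC_1.01_Gm13_34658945_C_A	Gm13	34658945	Re-orient	EW
BARC_1.01_Gm14_48713607_A_G	Gm14	48713607	BARC_1.01_Gm14_48755126_G_A	Gm14	48755126	Re-orient	WP
BARC_1.01_Gm15_25823658_T_C	Gm15	25823658	BARC_1.01_Gm15_36378430_A_G	Gm15	36378430	Re-orient	EW
BARC_1.01_Gm16_5856598_G_A	Gm16	5856598	BARC_1.01_Gm16_5887676_G_A	Gm16	5887676	Re-orient	WP
BARC_1.01_Gm16_17407537_T_G	Gm16	17407537	BARC_1.01_Gm16_22593496_G_A	Gm16	22593496	Re-orient	WP
BARC_1.01_Gm19_3021_T_C	Gm19	3021	BARC_1.01_Gm19_567731_A_G	Gm19	567731	Re-orient	WP
BARC_1.01_Gm20_7082863_T_G	Gm20	7082863	BARC_1.01_Gm20_7419439_G_A	Gm20	7419439	Re-orient	WP
BARC_1.01_Gm20_18531300_T_C	Gm20	18531300	BARC_1.01_Gm20_7419439_G_A	Gm20	20977430	Re-orient	WP
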