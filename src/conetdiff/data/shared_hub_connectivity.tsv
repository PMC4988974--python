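ortholog_id	transcript_a	K_i_a	transcript_b	K_i_b
AT2G33170.1	rsa_locus_20040_iso_1_len_628_ver_2	1	cra_locus_2641_iso_1_len_3992_ver_3	0.983
AT2G23755.1	rsa_locus_60320_iso_1_len_335_ver_2	0.996	cra_locus_34353_iso_1_len_643_ver_3	0.935
AT1G58420.1	rsa_locus_17189_iso_1_len_765_ver_2	0.977	cra_locus_10634_iso_1_len_763_ver_3	0.939
AT1G11050.1	rsa_locus_318_iso_2_len_3548_ver_2	0.919	cra_locus_2311_iso_1_len_4155_ver_3	0.906
AT4G22600.1	rsa_locus_21779_iso_1_len_1439_ver_2	0.917	cra_locus_18418_iso_1_len_1428_ver_3	0.906
AT2G15760.1	rsa_locus_1097_iso_3_len_975_ver_2	0.888	cra_locus_893_iso_1_len_1250_ver_3	0.811
AT3G07490.1	rsa_locus_13412_iso_1_len_521_ver_2	0.877	cra_locus_1192_iso_1_len_1528_ver_3	0.876
AT5G01830.1	rsa_locus_22614_iso_1_len_2313_ver_2	0.874	cra_locus_2457_iso_1_len_2491_ver_3	0.793
AT2G40000.1	rsa_locus_54630_iso_1_len_297_ver_2	0.852	cra_locus_566_iso_2_len_1446_ver_3	0.966
AT5G06710.1	rsa_locus_8304_iso_1_len_640_ver_2	0.828	cra_locus_16080_iso_1_len_1780_ver_3	0.727
AT1G76350.1	rsa_locus_6660_iso_2_len_1669_ver_2	0.819	cra_locus_1842_iso_1_len_1728_ver_3	0.952
AT3G57630.1	rsa_locus_13327_iso_2_len_2547_ver_2	0.785	cra_locus_3747_iso_1_len_3248_ver_3	0.929
AT5G67300.1	rsa_locus_1417_iso_2_len_1458_ver_2	0.735	cra_locus_94_iso_1_len_1200_ver_3	0.872
AT2G23290.1	rsa_locus_4970_iso_2_len_1415_ver_2	0.663	cra_locus_94_iso_3_len_769_ver_3	0.910
AT1G72520.1	rsa_locus_32_iso_6_len_1369_ver_2	0.653	cra_locus_842_iso_2_len_1157_ver_3	0.945
AT2G01300.1	rsa_locus_8505_iso_1_len_753_ver_2	0.622	cra_locus_10412_iso_1_len_790_ver_3	0.935
AT5G61510.1	rsa_locus_10177_iso_1_len_1131_ver_2	0.615	cra_locus_4109_iso_1_len_1183_ver_3	0.804
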