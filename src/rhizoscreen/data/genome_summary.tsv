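strain	group	size_mb	gc_pct	cds
R_yanglingense_CCBAU01603	FOCAL	7.67	59.0	8256
M_silamurunense_CCBAU01550	ACiM	7.07	62.7	7496
M_silamurunense_CCBAU45272	ACiM	7.22	63.1	7692
M_septentrionale_CCBAU01583	ACiM	7.67	62.1	7356
M_amorphae_CCBAU01570	ACiM	7.37	61.2	7141
M_caraganae_CCBAU01502	ACiM	7.20	62.4	7005
M_temperatum_CCBAU01399	ACiM	7.42	62.4	8604
M_metallidurans_STM2683	nonACiM	6.23	62.0	5962
M_ciceri_bv_biserrulae_WSM1271	nonACiM	6.70	61.7	6264
M_ciceri_ca181	nonACiM	6.42	61.5	6694
M_loti_MAFF303099	nonACiM	7.60	60.6	7281
Mesorhizobium_sp_WSM1293	nonACiM	6.94	61.8	6706
M_loti_R88b	nonACiM	7.20	62.4	7179
M_opportunistum_WSM2075	nonACiM	6.88	62.9	6508
M_ciceri_WSM4083	nonACiM	6.84	61.3	6616
R_etli_CFN42	nonACiR	6.53	60.5	6156
Rhizobium_sp_BR816	nonACiR	6.95	60.4	6752
R_etli_bv_mimosae_Mim1	nonACiR	7.20	60.4	6792
R_leguminosarum_bv_trifolii_WSM2304	nonACiR	5.87	60.6	6415
Rhizobium_sp_IRBG74	nonACiR	5.46	58.7	5478
R_leguminosarum_bv_phaseoli_4292	nonACiR	7.35	60.2	7177
B_japonicum_USDA6	OUTGROUP	9.21	63.7	8409
C_taiwanensis_LMG19424	OUTGROUP	6.48	65.03	5654
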