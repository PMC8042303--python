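gene_id	ensembl_id	cre	cell_type	fdr	tag_snp	rsid	snp_p	trait	Myeloid	Bcell	Tcell	Epithelial	Fibroblast	Endothelial
PSORS1C2	ENSG00000204538.3	chr6:30848819-30857882	Epithelial	3.16E-02	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.447	-0.447	-0.447	2.236	-0.447	-0.447
SFTA2	ENSG00000196260.3	chr6:30848819-30857882	Epithelial	3.16E-02	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.412	-0.457	-0.448	2.236	-0.465	-0.454
DPCR1	ENSG00000168631.7	chr6:30848819-30857882	Epithelial	3.16E-02	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.442	-0.451	-0.461	2.236	-0.408	-0.474
MUC21	ENSG00000204544.5	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.399	-0.469	-0.431	2.235	-0.462	-0.476
DDR1	ENSG00000204580.7	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.467	-0.456	-0.509	2.232	-0.323	-0.477
MUC22	ENSG00000261272.1	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.442	-0.497	-0.299	2.231	-0.497	-0.497
DGKD	ENSG00000077044.5	chr2:233453904-233458464	Epithelial	1.07E-03	chr2.233426526	rs1656402	8.00E-08	Non-small cell lung cancer (survival)	-0.486	-0.105	-0.336	2.197	-0.681	-0.589
POU5F1	ENSG00000204531.11	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.696	-0.595	-0.630	2.066	-0.565	0.419
CCHCR1	ENSG00000204536.9	chr6:30848819-30857882	Epithelial	3.16E-02	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.685	-0.730	-0.680	2.062	0.392	-0.358
PSORS1C1	ENSG00000204540.6	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.737	-0.777	-0.783	2.052	0.090	0.155
VARS2	ENSG00000137411.12	chr6:30848819-30857882	Epithelial	3.16E-02	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.370	-0.835	-1.131	1.951	0.240	0.144
TIGD1	ENSG00000221944.3	chr2:233453904-233458464	Epithelial	1.07E-03	chr2.233426526	rs1656402	8.00E-08	Non-small cell lung cancer (survival)	-1.161	-0.796	0.255	1.939	-0.406	0.169
KLHDC10	ENSG00000128607.9	chr7:130666628-130685063	Epithelial	2.00E-02	chr7.130668618	rs6957511	1.00E-06	Squamous cell lung carcinoma	-0.355	-1.310	-1.074	1.491	0.584	0.665
CHRND	ENSG00000135902.5	chr2:233453904-233458464	Epithelial	1.07E-03	chr2.233426526	rs1656402	8.00E-08	Non-small cell lung cancer (survival)	0.534	-0.964	0.910	1.449	-0.964	-0.964
C6orf15	ENSG00000204542.2	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.770	-0.770	-0.505	1.368	-0.770	1.352
PRR3	ENSG00000204576.7	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.377	-1.297	-0.856	1.269	1.131	-0.090
GIGYF2	ENSG00000204120.10	chr2:233453904-233458464	Epithelial	1.07E-03	chr2.233426526	rs1656402	8.00E-08	Non-small cell lung cancer (survival)	-0.487	-1.368	-1.013	1.242	0.815	0.811
ZNF322	ENSG00000181315.6	chr6:27094480-27096156	Epithelial	2.58E-02	chr6.26686131	rs10456332	7.00E-06	Small cell lung carcinoma	-0.550	-1.106	-1.227	1.209	1.067	0.606
MDC1	ENSG00000137337.10	chr6:30889573-30895783	Epithelial	1.61E-05	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	-0.883	-1.281	-0.782	1.178	0.974	0.794
HYLS1	ENSG00000198331.6	chr11:125543549-125544766	Endothelial	9.66E-04	chr11.125510257	rs113301858	7.00E-06	Squamous cell lung carcinoma	-1.371	-0.807	0.263	-0.207	0.318	1.804
IL1R1	ENSG00000115594.7	chr2:102854553-102858050	Fibroblast	3.09E-02	chr2.102857739	rs185815317	1.00E-06	Familial squamous cell lung carcinoma	-0.792	-1.055	-1.004	0.611	1.550	0.689
BLOC1S2	ENSG00000196072.7	chr10:102012793-102017699	Myeloid	1.79E-04	chr10.102048979	rs12765052	1.00E-06	Squamous cell lung carcinoma	2.161	-0.253	-0.008	-0.780	-0.438	-0.682
CLEC4E	ENSG00000166523.3	chr12:9052330-9056220	Myeloid	3.18E-02	chr12.9058562	rs1073160	3.00E-06	Small cell lung carcinoma	1.837	-0.689	-0.678	-0.657	-0.695	0.882
CD84	ENSG00000066294.10	chr1:160315750-160319868	Myeloid	2.06E-02	chr1.160210727	rs2369473	7.00E-06	Squamous cell lung carcinoma	1.760	-0.255	0.928	-0.812	-0.814	-0.808
CHUK	ENSG00000213341.6	chr10:101951673-101953324	Myeloid	1.17E-02	chr10.102048979	rs12765052	1.00E-06	Squamous cell lung carcinoma	1.459	-1.436	-0.536	1.058	-0.629	0.084
PPP1R18	ENSG00000146112.7	chr6:30802423-30803200	Tcell	2.70E-04	chr6.30882415	rs114274879	3.00E-16	Squamous cell lung carcinoma	0.965	-0.295	1.539	-1.526	-0.501	-0.183
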