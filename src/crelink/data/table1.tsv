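tag_snp	rsid	snp_p	trait	cre	fdr	cell_type
chr1.160210727	rs2369473	7.00e-06	Squamous cell lung carcinoma	chr1:160315750-160319868	3.07e-02	Myeloid
chr10.102048979	rs12765052	1.00e-06	Squamous cell lung carcinoma	chr10:101923384-101944862	3.86e-02	Myeloid
chr10.101946033	rs28372851	5.00e-07	Squamous cell lung carcinoma	chr10:101951673-101953324	1.04e-02	Myeloid
chr10.102048979	rs12765052	1.00e-06	Squamous cell lung carcinoma	chr10:101951673-101953324	1.04e-02	Myeloid
chr10.101946033	rs28372851	5.00e-07	Squamous cell lung carcinoma	chr10:102012793-102017699	1.20e-04	Myeloid
chr10.102048979	rs12765052	1.00e-06	Squamous cell lung carcinoma	chr10:102012793-102017699	1.20e-04	Myeloid
chr10.101946033	rs28372851	5.00e-07	Squamous cell lung carcinoma	chr10:102049789-102052812	8.65e-06	Myeloid
chr10.102048979	rs12765052	1.00e-06	Squamous cell lung carcinoma	chr10:102049789-102052812	8.65e-06	Myeloid
chr11.94284529	rs12279741	8.00e-06	Small cell lung carcinoma	chr11:94279690-94284377	8.37e-04	Myeloid
chr12.9058562	rs1073160	3.00e-06	Small cell lung carcinoma	chr12:9052330-9056220	4.30e-02	Myeloid
chr15.58418128	rs2704201	4.00e-06	Small cell lung carcinoma	chr15:58434184-58441657	2.98e-06	Myeloid
chr6.26403036	rs12200782	1.00e-06	Small cell lung carcinoma	chr6:26393324-26393714	3.84e-02	Myeloid
chr6.26581258	rs141670911	1.00e-06	Small cell lung carcinoma	chr6:26393324-26393714	3.84e-02	Myeloid
chr10.4961021	rs4453114	2.00e-06	Squamous cell lung carcinoma	chr10:5003981-5007221	1.96e-02	Epithelial
chr2.17784157	rs13031455	2.00e-06	Squamous cell lung carcinoma	chr2:17801191-17803176	1.15e-06	Epithelial
chr2.233426526	rs1656402	8.00e-08	Non-small cell lung cancer (survival)	chr2:233453904-233458464	4.15e-03	Epithelial
chr5.72305846	rs258892	5.00e-06	Small cell lung carcinoma	chr5:72083963-72085536	1.41e-03	Epithelial
chr6.10415006	rs654351	2.00e-06	Squamous cell lung carcinoma	chr6:10399644-10415402	1.50e-02	Epithelial
chr6.26581258	rs141670911	1.00e-06	Small cell lung carcinoma	chr6:26462575-26465582	3.46e-02	Epithelial
chr6.26651053	rs13201782	2.00e-08	Squamous cell lung carcinoma	chr6:26462575-26465582	3.46e-02	Epithelial
chr6.26686131	rs10456332	7.00e-06	Small cell lung carcinoma	chr6:26462575-26465582	3.46e-02	Epithelial
chr6.30882415	rs114274879	3.00e-16	Squamous cell lung carcinoma	chr6:30848819-30857882	4.56e-02	Epithelial
chr6.30882415	rs114274879	3.00e-16	Squamous cell lung carcinoma	chr6:30889573-30895783	2.35e-03	Epithelial
chr2.65832377	rs840781	8.00e-07	Familial squamous cell lung carcinoma	chr2:65832165-65835046	1.09e-03	Bcell
chr3.194858374	rs2131877	2.00e-08	Non-small cell lung cancer	chr3:194848773-194855042	7.36e-03	Bcell
chr6.32605884	rs74942078	3.00e-17	Squamous cell lung carcinoma	chr6:32568908-32579990	2.98e-02	Bcell
chr6.32591476	rs112037939	2.00e-06	Small cell lung carcinoma	chr6:32599939-32607692	6.99e-04	Bcell
chr6.32605884	rs74942078	3.00e-17	Squamous cell lung carcinoma	chr6:32599939-32607692	6.99e-04	Bcell
chr6.32605884	rs74942078	3.00e-17	Squamous cell lung carcinoma	chr6:32652218-32660026	2.53e-03	Bcell
chr21.40173528	rs1209950	3.00e-07	Non-small cell lung cancer (survival)	chr21:40169204-40174398	4.52e-02	Cancer
chr5.82418056	rs28745309	5.00e-06	Squamous cell lung carcinoma	chr5:82420842-82421162	4.56e-02	Cancer
chr6.26328353	rs34107459	1.00e-10	Squamous cell lung carcinoma	chr6:26327078-26331665	1.11e-02	Cancer
chr6.26686131	rs10456332	7.00e-06	Small cell lung carcinoma	chr6:26757238-26758412	3.93e-04	Cancer
chr6.26686131	rs10456332	7.00e-06	Small cell lung carcinoma	chr6:27144603-27146930	3.24e-02	Cancer
chr11.125510257	rs113301858	7.00e-06	Squamous cell lung carcinoma	chr11:125543549-125544766	1.41e-03	Endothelial
chr2.152481712	rs10174077	1.00e-06	Squamous cell lung carcinoma	chr2:152474585-152476605	2.78e-06	Endothelial
chr2.225263527	rs6714462	8.00e-06	Familial squamous cell lung carcinoma	chr2:225270125-225272718	1.63e-02	Endothelial
chr5.72305846	rs258892	5.00e-06	Small cell lung carcinoma	chr5:72166471-72170755	2.59e-03	Endothelial
chr6.7770511	rs140013431	1.00e-06	Small cell lung carcinoma	chr6:7770218-7770887	4.90e-02	Endothelial
chr6.34923864	rs847845	6.00e-06	Non-small cell lung cancer	chr6:34938580-34938872	5.21e-03	Fibroblast
chr6.30882415	rs114274879	3.00e-16	Squamous cell lung carcinoma	chr6:30802423-30803200	9.81e-04	Tcell
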