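SNP1	Pos1	Gene1	SNP2	Pos2	Gene2	LD	P_SNP1	P_SNP2	P_SNP1xSNP2	P_SNP1xSNP2_Cond	P_SNP1_rep	P_SNP2_rep	P_SNP1xSNP2_rep	P_SNP1xSNP2_Cond_rep
rs532098	32610275	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.197	2.22E-33	2.88E-10	7.83E-21	3.12E-21	9.74E-30	2.30E-10	2.16E-08	4.79E-03
rs13207945	32611931	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.196	1.74E-33	2.88E-10	1.17E-20	3.56E-21	7.98E-30	2.30E-10	2.11E-08	4.61E-03
rs482044	32608287	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.162	2.21E-22	2.88E-10	3.60E-21	4.28E-16	2.57E-21	2.30E-10	4.34E-09	5.39E-03
rs9272143	32633026	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.103	3.10E-13	2.88E-10	3.14E-43	2.14E-12	2.29E-08	2.30E-10	2.25E-29	3.15E-03
rs3852215	32667724	~HLA-DQB1	rs7744001	32658309	~HLA-DQB1-AS1	0.021	2.33E-08	7.26E-08	7.50E-14	3.11E-11	3.71E-11	7.80E-04	1.11E-04	4.07E-05
rs7774434	32689801	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.023	8.43E-06	2.88E-10	3.30E-22	1.21E-10	8.12E-07	2.30E-10	4.22E-13	8.51E-03
rs9272143	32633026	NA	rs7744001	32658309	~HLA-DQB1-AS1	0.003	3.10E-13	7.26E-08	1.27E-16	2.07E-10	2.29E-08	7.80E-04	6.65E-10	1.96E-03
rs9272105	32632222	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.067	7.53E-14	2.88E-10	1.10E-39	6.76E-10	9.78E-08	2.30E-10	8.96E-26	2.36E-02
rs1964995	32481634	NA	rs6928482	32658472	~HLA-DQB1-AS1	0.133	9.64E-25	2.88E-10	2.76E-23	3.32E-09	2.33E-12	2.30E-10	1.26E-09	1.05E-01
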