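name	gene	maf_case_blood	maf_case_tumor	maf_control_internal	maf_external	tri_allelic
rs10802602	RYR2	0.038	0.033	0.396	0.223	False
rs2618671	RYR2	0.325	0.309	0.571	0.567	False
rs2779420	RYR2	0.301	0.293	0.536	0.483	False
rs13030271	LRP1B	0.082	0.115	0.378	0.000	False
rs10166768_C_T	LRP1B	0.179	0.230	0.677	0.179	True
rs10166768_C_G	LRP1B	0.500	0.321	0.000	0.493	True
rs10179937	FN1	0.088	0.078	0.749		False
rs200077102	FN1	0.076	0.065	0.749	0.415	False
rs7682763	EPHA5	0.258	0.250	0.716		False
rs13311049	SDK1	0.099	0.109	0.389	0.164	False
rs13311637	SDK1	0.067	0.063	0.508	0.024	False
rs611655	MMD2_RADIL	0.005	0.025	0.438	0.000	False
rs12543616	RUNX1T1	0.189	0.224	0.760	0.487	False
rs10956571	ADCY8	0.253	0.240	0.629	0.553	False
rs200093832	TRPM3	0.267	0.189	0.535	0.718	False
rs61909780	CNTN5	0.027	0.025	0.388	0.141	False
rs78588384	CNTN5	0.045	0.055	0.369	0.298	False
rs1987574	SERPINA1	0.200	0.268	0.731		False
rs78393784	SERPINA1	0.386	0.312	0.294		False
rs370565365	ACSM2A	0.053		0.252	0.020	False
rs112385920	CD70	0.507	0.513	0.792	0.816	False
rs2076859	RUNX1	0.081	0.117	0.827		False
rs3989120	RUNX1	0.220	0.214	0.827	0.000	False
rs13046555	RUNX1	0.150	0.222	0.321	0.462	False
rs778825437	PCDH11X	0.038	0.033	0.396		False
rs2754876	PCDH11X	0.187	0.207	0.650	0.369	False
rs2750652	PCDH11X	0.392	0.400	0.730	0.357	False
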