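genome_id	gene_id	contig_id	gene_index	role	rebase_hit	identity_pct	motif	mod_type	rm_type	fused_re	rm_system_reported	motif_detected_reported
BS3	EMGBS3_04270	BS3_ctg1	427	M	M.SstE37II	58.9	GmANTC	m6A	II	0	No	Yes
BS3	EMGBS3_09240	BS3_ctg1	924	M	M.Sth20745I	71.4	TTAmA	m6A	II	0	No	Yes
BS3	EMGBS3_12600	BS3_ctg1	1260	M	M1.BceSIII	22.9	AmCGGC	m4C	II	0	No	No
BS6	EMGBS6_08960	BS6_ctg1	896	M	M.SinI	57.0	GGWmCC	m5C	II	0	No	No
BS8	EMGBS8_10720	BS8_ctg1	1072	R	DvuI	36.3	?	unknown	I	0	-	-
BS8	EMGBS8_10740	BS8_ctg1	1074	S	S.PveNS15I	32.4	?	unknown	I	0	-	-
BS8	EMGBS8_10750	BS8_ctg1	1075	M	M.RbaNRL2II	55.6	ACGmANNNNNNGRTC	m6A	I	0	Yes	No
BS10	EMGBS10_10070	BS10_ctg1	1007	M	M.CjeFIII	23.7	GCAmAGG	m6A	II	1	Yes	No
BS14	EMGBS14_10020	BS14_ctg1	1002	M	M.Bsp460I	56.7	GmANTC	m6A	II	0	No	Yes
BS15	EMGBS15_02830	BS15_ctg1	283	M	M.Bli37I	56.6	GmAYNNNNNRTC	m6A	I	0	Yes	No
BS15	EMGBS15_02840	BS15_ctg1	284	M	M.EcoNIH1III	59.2	GmATGNNNNNNTAC	m6A	I	0	Yes	No
BS15	EMGBS15_02870	BS15_ctg1	287	S	S.PveNS15I	47.2	?	unknown	I	0	-	-
BS15	EMGBS15_02930	BS15_ctg1	293	R	DvuI	38.4	?	unknown	I	0	-	-
BS15	EMGBS15_03820	BS15_ctg1	382	M	M.EcoGI	25.8	nonspecific	m6A	II	0	Yes	No
BS15	EMGBS15_03830	BS15_ctg1	383	R	XmnI	34.0	GAANNNNTTC	unknown	II	0	-	-
BS15	EMGBS15_04560	BS15_ctg1	456	R	GmeII	33.8	TCCAGG	unknown	III	0	-	-
BS15	EMGBS15_04600	BS15_ctg1	460	M	M.FpsJII	53.4	CGCmAG	m6A	III	0	Yes	No
BS15	EMGBS15_05670	BS15_ctg1	567	M	M.FnuDI	59.8	GGmCC	m4C	II	0	Yes	No
BS15	EMGBS15_05690	BS15_ctg1	569	R	BhaII	45.6	GGCC	unknown	II	0	-	-
BS15	EMGBS15_12460	BS15_ctg1	1246	M	M.Mva1261II	37.1	CTmANNNNNNRTTC	m6A	I	0	No	No
BD1	EMGBD1_08400	BD1_ctg1	840	M	M.Sth20745I	71.0	TTAmA	m6A	II	0	No	Yes
BD1	EMGBD1_09320	BD1_ctg1	932	M	M1.BceSIII	22.9	AmCGGC	m4C	II	0	No	No
BD1	EMGBD1_19510	BD1_ctg1	1951	M	M.SstE37II	58.9	GmANTC	m6A	II	0	No	Yes
BD2	EMGBD2_08760	BD2_ctg1	876	M	M.HgiDII	55.0	GTmCGAC	m5C	II	0	Yes	No
BD2	EMGBD2_08790	BD2_ctg1	879	M	M.AquIV	28.5	GRGGAmAG	m6A	II	1	Yes	No
BD2	EMGBD2_08800	BD2_ctg1	880	R	LpnPI	56.3	CCDG	unknown	II	0	-	-
BD3	EMGBD3_00670	BD3_ctg1	67	M	M.Mma5219II	45.9	AGmCT	m4C	II	0	No	Yes
BD3	EMGBD3_01960	BD3_ctg1	196	M	M.AvaVI	50.3	GmATC	m6A	II	0	No	Yes
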