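genome_id	motif	meth_offset	mod_type	in_rebase	n_meth_sites	n_motif_sites	ratio_pct	mean_qv	mean_subread_cov
BS1	GANTC	1	m6A	Yes	1813	2070	87.6	58.0	35.2
BS1	TTAA	3	m6A	Yes	1264	1522	83.0	55.5	34.1
BS1	GCWGC	1	m4C	Yes	3026	15948	19.0	38.4	40.6
BS3	GANTC	1	m6A	Yes	3724	4014	92.8	66.1	41.3
BS3	TTAA	3	m6A	Yes	3036	3338	91.0	62.4	40.4
BS3	GCWGC	1	m4C	Yes	13821	54026	25.6	39.5	46.4
BS8	AGGNNNNNRTTT	0	m6A	No	80	276	29.0	39.6	65.8
BS10	ACGAG	3	m6A	No	1986	7185	27.6	45.0	171.4
BS12	GMAGCTKC	4	m4C	No	169	220	76.8	50.9	83.5
BS12	HCAGCTKC	4	m4C	No	124	293	42.3	46.8	79.0
BS12	BGMAGCTGD	5	m4C	No	78	185	42.2	46.3	76.3
BS14	GANTC	1	m6A	Yes	2856	2880	99.2	190.6	166.9
BS15	GAANNNNTTC	1	m6A	Yes	1309	1472	88.9	55.6	30.9
BS15	AGCNNNNNNCAT	0	m6A	No	642	726	88.4	56.0	29.4
BS15	ATGNNNNNNGCT	0	m6A	No	619	726	85.3	52.0	29.8
BS15	AGCNNNNNNGTG	0	m6A	No	311	349	89.1	56.9	30.4
BS15	CACNNNNNNGCT	1	m6A	No	293	349	84.0	53.3	30.9
BS15	CAANNNNNNNNCTTG	2	m6A	No	205	256	80.1	49.4	29.1
BS15	CAAGNNNNNNNDTTG	2	m6A	No	164	214	76.6	48.7	28.7
BS15	TTAGNNNNNCCT	2	m6A	No	87	99	87.9	51.3	29.8
BS15	AGGNNNNNCTAA	0	m6A	No	77	99	77.8	49.4	29.7
BS15	GYTANNNNNNNTTRG	3	m6A	No	76	89	85.4	56.0	31.3
BS15	CYAANNNNNNNTAVCH	3	m6A	No	59	127	46.5	53.5	32.6
BD1	GCWGC	1	m4C	Yes	72730	77932	93.3	140.2	297.3
BD1	GANTC	1	m6A	Yes	6754	6844	98.7	346.3	281.7
BD1	TTAA	3	m6A	Yes	5475	5564	98.4	325.3	270.9
BD2	TANGGAB	5	m6A	No	1276	1367	93.3	64.4	48.5
BD3	GATC	1	m6A	Yes	9446	9618	98.2	122.1	93.7
BD3	AGCT	2	m4C	Yes	5974	6224	96.0	84.0	92.1
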