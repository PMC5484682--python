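mirna_id	gene_symbol	mirsvr_score	pair_rho	pair_adj_p
miR-23a	EFHA2	-1.260	-0.589	3.42e-05
miR-23a	GALNT12	-1.264	-0.480	1.78e-03
miR-23a	SATB1	-1.342	-0.454	3.75e-03
miR-23a	STAT4	-1.276	-0.475	2.12e-03
miR-23a	TMEM263	-1.201	-0.459	3.26e-03
miR-23b	EFHA2	-1.260	-0.531	3.49e-04
miR-23b	GALNT12	-1.264	-0.438	5.75e-03
miR-30c	ITGA6	-1.203	-0.433	6.46e-03
miR-93	FIGNL1	-1.231	-0.463	2.91e-03
miR-93	MBTPS1	-1.228	-0.533	3.23e-04
miR-93	MTERFD2	-1.231	-0.540	2.51e-04
miR-93	URI1	-1.273	-0.468	2.57e-03
miR-93	ZFYVE9	-1.332	-0.511	7.03e-04
miR-143	ATP10A	-1.333	-0.443	5.05e-03
miR-185	SORCS3	-1.215	-0.437	5.79e-03
miR-196a*	ADORA3	-1.270	-0.472	2.30e-03
miR-223	CBLB	-1.252	-0.447	4.50e-03
miR-223	ERCC6L2	-1.296	-0.446	4.63e-03
miR-223	IL6ST	-1.340	-0.432	6.53e-03
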