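feature_id	rho	adj_p
ADORA3	0.463	3.04e-04
ATP10A	-0.541	3.58e-05
CBLB	-0.483	1.75e-04
EFHA2	-0.505	9.48e-05
ERCC6L2	-0.508	8.92e-05
FIGNL1	-0.565	1.77e-05
GALNT12	-0.688	7.40e-08
IL6ST	-0.470	2.52e-04
ITGA6	-0.510	8.18e-05
MBTPS1	-0.512	7.89e-05
MTERFD2	-0.533	4.31e-05
SATB1	-0.457	3.65e-04
SORCS3	-0.457	3.62e-04
STAT4	-0.500	1.11e-04
TMEM263	-0.463	3.06e-04
URI1	-0.503	1.01e-04
ZFYVE9	-0.478	2.01e-04
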