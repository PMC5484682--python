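feature_id	rho	adj_p
miR-23a	0.377	1.91e-02
miR-23b	0.405	1.33e-02
miR-30c	0.344	3.44e-02
miR-93	0.386	1.78e-02
miR-143	0.378	1.91e-02
miR-185	0.363	2.43e-02
miR-196a*	-0.393	1.60e-02
miR-223	0.346	3.44e-02
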