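class	oc_min	oc_max	hc_min	hc_max
Lipid	0.0	0.3	1.5	2.5
Unsaturated Hydrocarbon	0.0	0.125	0.8	1.5
Protein	0.3	0.55	1.5	2.3
Amino Sugar	0.55	0.7	1.5	2.2
Carbohydrate	0.7	1.5	1.5	2.5
Lignin	0.125	0.65	0.8	1.5
Tannin	0.65	1.1	0.8	1.5
Condensed Hydrocarbon	0.0	0.95	0.2	0.8
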