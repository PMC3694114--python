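gene_id	symbol	log2ratio	pvalue	adjusted_pvalue	position
ENSG00000151503	NCAPD3	5.58	0.0	0.0	1
ENSG00000096060	FKBP5	5.08	0.0	0.0	2
ENSG00000116133	DHCR24	3.38	0.0	0.0	3
ENSG00000156689	GLYATL2	3.39	1.83E-317	1.47E-313	4
ENSG00000113594	LIFR	4.24	7.33E-311	4.72E-307	5
ENSG00000166451	CENPN	5.09	3.96E-299	2.12E-295	6
ENSG00000115648	MLPH	2.69	2.81E-286	1.29E-282	7
ENSG00000244324	RP11-67L3.6	3.59	7.97E-235	3.21E-231	8
ENSG00000116285	ERRFI1	4.26	1.44E-226	5.14E-223	9
ENSG00000130066	SAT1	2.93	3.58E-197	1.15E-193	10
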