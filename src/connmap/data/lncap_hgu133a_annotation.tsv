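gene_id	probe_id
ENSG00000151503	212789_at
ENSG00000096060	204560_at
ENSG00000116133	200862_at
ENSG00000113594	205876_at
ENSG00000166451	219555_s_at
ENSG00000166451	222118_at
ENSG00000115648	218211_s_at
ENSG00000130066	213988_s_at
ENSG00000130066	210592_s_at
ENSG00000130066	203455_s_at
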