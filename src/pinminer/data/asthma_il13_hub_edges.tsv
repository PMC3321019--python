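protein_1	protein_2	n_links
IL17A	IL13	2
IL4	MAPK21	1
IL4	STAT6	1
IL4	FLG	1
AHR	GRP	1
FOXRED1	IL13	1
GRPR	GRP	1
IL13	TSLP	1
IL13	STAT6	1
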