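term	source	k	K	p_raw	p_adj	genes_found	groups
TERM0008	synthetic	2	9	0.0306122	0.0467687	G000008;G000062	0
TERM0019	synthetic	2	11	0.0467687	0.0467687	G000008;G000062	1
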