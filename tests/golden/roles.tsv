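network	gene	role	in_shared_hubs	in_shared_bottlenecks	is_key_gene
genes_a	G000061	hub	1	1	0
genes_a	G000062	hub	1	1	1
genes_a	G000008	bottleneck	0	0	1
genes_a	G000061	bottleneck	1	1	0
genes_a	G000062	bottleneck	1	1	1
genes_a	G000061	hub_bottleneck	1	1	0
genes_a	G000062	hub_bottleneck	1	1	1
genes_b	G000061	hub	1	1	0
genes_b	G000062	hub	1	1	1
genes_b	G000061	bottleneck	1	1	0
genes_b	G000062	bottleneck	1	1	1
genes_b	G000061	hub_bottleneck	1	1	0
genes_b	G000062	hub_bottleneck	1	1	1
common	G000008	bottleneck	0	0	1
common	G000062	bottleneck	1	1	1
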