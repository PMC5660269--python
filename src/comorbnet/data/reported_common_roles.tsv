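# Hub and bottleneck genes reported for the 99-node common-gene network
# (degree for hubs, normalized betweenness for bottlenecks).
hub	hub_degree	bottleneck	bottleneck_betweenness
JAK2	25	JAK2	0.160941
TLR4	22	TP53	0.10348
TP53	19	AGT	0.102813
TLR2	18	CYP3A4	0.083948
STAT3	16	TLR4	0.083942
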