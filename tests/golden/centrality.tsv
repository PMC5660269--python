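gene	degree	betweenness	is_hub	is_bottleneck	is_hub_bottleneck
G000001	11	0.00986334	0	0	0
G000002	10	0.000356506	0	0	0
G000003	10	0.00968509	0	0	0
G000004	10	0.00968509	0	0	0
G000005	11	0.00986334	0	0	0
G000006	10	0.00968509	0	0	0
G000007	11	0.00986334	0	0	0
G000008	11	0.453565	0	1	0
G000009	11	0.00986334	0	0	0
G000010	11	0.00986334	0	0	0
G000011	10	0.00968509	0	0	0
G000012	10	0.000356506	0	0	0
G000014	3	0.0693277	0	0	0
G000016	2	0.128342	0	0	0
G000021	1	0	0	0	0
G000024	4	0.126369	0	0	0
G000032	2	0.0105042	0	0	0
G000033	1	0	0	0	0
G000035	2	0.0105042	0	0	0
G000036	1	0	0	0	0
G000037	1	0	0	0	0
G000038	1	0	0	0	0
G000039	2	0.0105042	0	0	0
G000043	1	0	0	0	0
G000044	2	0.0588235	0	0	0
G000048	2	0.0105042	0	0	0
G000049	1	0	0	0	0
G000050	1	0	0	0	0
G000051	3	0.332697	0	0	0
G000056	1	0	0	0	0
G000058	1	0	0	0	0
G000059	1	0	0	0	0
G000060	1	0	0	0	0
G000061	12	0.377005	0	0	0
G000062	12	0.465686	0	1	0
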