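cluster_id	size	cohesiveness	p_value	members
0	23	0.933333	1.6314e-09	G000014;G000016;G000021;G000024;G000032;G000033;G000035;G000036;G000037;G000038;G000039;G000043;G000044;G000048;G000049;G000050;G000051;G000056;G000058;G000059;G000060;G000061;G000062
1	13	0.969231	3.51043e-06	G000001;G000002;G000003;G000004;G000005;G000006;G000007;G000008;G000009;G000010;G000011;G000012;G000016
2	11	0.555556	0.0173892	G000016;G000032;G000035;G000039;G000043;G000044;G000048;G000049;G000050;G000060;G000062
3	10	0.5625	0.0218628	G000021;G000032;G000035;G000036;G000037;G000039;G000048;G000056;G000059;G000061
4	3	0.5	0.3	G000024;G000033;G000058
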