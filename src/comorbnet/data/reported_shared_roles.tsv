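# Shared hub and bottleneck genes reported for the separate IBD and NASH
# interactomes (54 shared hubs with degree; 3 shared bottlenecks with
# betweenness).  "starred" marks genes also listed for the common network.
hub	hub_degree	starred	bottleneck	bottleneck_betweenness
GMPS	3	0	SIRT1	0.116186
PRKAG2	12	0	TP53	0.100492
MLST8	9	0	HIF1A	0.086405
MTOR	18	0		
MAP3K7	22	0		
TRAF6	19	0		
PRKAG1	12	0		
PRKAB1	13	0		
PRKAB2	12	0		
ACTB	3	0		
ACTG1	4	0		
PRKAA2	14	0		
SERPINC1	5	0		
F2	7	0		
RPTOR	18	0		
TLR4	17	1		
IKBKG	18	0		
BIRC3	12	0		
TRAF3	11	0		
TICAM1	11	0		
UBE2N	12	0		
BIRC2	14	0		
MYD88	15	0		
IKBKB	21	0		
SERPIND1	5	0		
FGG	11	0		
PRKAA1	16	0		
TP53	20	1		
CREBBP	22	0		
MDM4	5	0		
HIF1A	10	0		
CD14	12	0		
TLR2	18	1		
AGT	9	1		
TERT	6	0		
STAT3	17	1		
JAK2	20	1		
HMGB1	9	0		
SIRT1	9	0		
PPARG	9	0		
VEGFA	8	0		
LEP	11	0		
IL6	3	0		
IGF1	6	0		
IL1B	8	0		
TGFB1	11	0		
IFNG	4	0		
SERPINE1	7	0		
IL4	3	0		
CSF2	4	0		
APOB	7	0		
GH1	3	0		
TEK	11	0		
CYP3A4	2	1		
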