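# Reported enriched-term table for the seven-gene key set: term, ontology
# source, adjusted p, associated genes found, and the printed group label
# (blank where the printed table carried the group over from the row above).
term	source	p_adj	genes_found	group
Association of TriC/CCT with target proteins during biosynthesis	REACTOME	160.0E-6	STAT3;TP53	0
IL-6 signaling pathway	WikiPathways	7.1E-6	AGT;JAK2;STAT3	1
activation of JAK2 kinase activity	GO_BiologicalProcess	100.0E-6	AGT;JAK2	
regulation of reactive oxygen species biosynthetic process	GO_BiologicalProcess	180.0E-9	AGT;JAK2;STAT3;TLR4	
type 1 angiotensin receptor binding	GO_MolecularFunction	100.0E-6	AGT;JAK2	
positive regulation of vascular smooth muscle cell proliferation	GO_BiologicalProcess	210.0E-6	AGT;JAK2	
positive regulation of nitric oxide biosynthetic process	GO_BiologicalProcess	8.3E-6	AGT;JAK2;TLR4	
regulation of cardiac muscle cell apoptotic process	GO_BiologicalProcess	210.0E-6	AGT;JAK2	
Toll-like Receptor Signaling	WikiPathways	170.0E-6	TLR2;TLR4	2
Simplified depiction of MYD88 distinct input-output pathway	WikiPathways	190.0E-6	TLR2;TLR4	
ApoE and miR-146 in inflammation and atherosclerosis	WikiPathways	62.0E-6	TLR2;TLR4	
detection of other organism	GO_BiologicalProcess	170.0E-6	TLR2;TLR4	
lipopolysaccharide receptor activity	GO_MolecularFunction	18.0E-6	TLR2;TLR4	
detection of molecule of bacterial origin	GO_BiologicalProcess	110.0E-6	TLR2;TLR4	
positive regulation of nitric-oxide synthase biosynthetic process	GO_BiologicalProcess	220.0E-9	JAK2;TLR2;TLR4	
cellular response to lipoteichoic acid	GO_BiologicalProcess	100.0E-6	TLR2;TLR4	
IL-5 Signaling Pathway	WikiPathways	90.0E-6	JAK2;STAT3	3
Physiological and Pathological Hypertrophy of the Heart	WikiPathways	240.0E-6	AGT;STAT3	
IL17 signaling pathway	WikiPathways	210.0E-6	JAK2;STAT3	
IL-6 signaling pathway	WikiPathways	7.1E-6	AGT;JAK2;STAT3	
Leptin Insulin Overlap	WikiPathways	170.0E-6	JAK2;STAT3	
EPO Receptor Signaling	WikiPathways	220.0E-6	JAK2;STAT3	
Serotonin Receptor 2 and STAT3 Signaling	WikiPathways	11.0E-6	JAK2;STAT3	
Growth hormone receptor signaling	REACTOME	210.0E-6	JAK2;STAT3	
activation of JAK2 kinase activity	GO_BiologicalProcess	100.0E-6	AGT;JAK2	
regulation of reactive oxygen species biosynthetic process	GO_BiologicalProcess	180.0E-9	AGT;JAK2;STAT3;TLR4	
type 1 angiotensin receptor binding	GO_MolecularFunction	100.0E-6	AGT;JAK2	
positive regulation of vascular smooth muscle cell proliferation	GO_BiologicalProcess	210.0E-6	AGT;JAK2	
JAK-STAT cascade involved in growth hormone signaling pathway	GO_BiologicalProcess	160.0E-6	JAK2;STAT3	
regulation of cardiac muscle cell apoptotic process	GO_BiologicalProcess	210.0E-6	AGT;JAK2	
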