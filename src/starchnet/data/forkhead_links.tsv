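source	target	target_name
R1	R2	eicosanoid signaling pathway
R1	R3	fatty acid beta degradation pathway
R1	R5	gluconeogenesis pathway
R1	R8	cholesterol biosynthetic pathway
R1	R17	vascular endothelial growth factor signaling pathway
R1	R21	coagulation cascade pathway
R1	R28	glycolysis pathway
R1	R30	amyotrophic lateral sclerosis disease pathway
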