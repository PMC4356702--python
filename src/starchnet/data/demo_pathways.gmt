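R1	forkhead class A signaling pathway	Foxa1	Igfbp1	Hnf4a	G6pc	Gck	Pck1	Hadh
R2	eicosanoid signaling pathway	Ccl2	Cxcl10	Src	Pparg
R3	fatty acid beta degradation pathway	Cpt1a	Hadh	Acaa1a	Bdh1	Acsl6
R5	gluconeogenesis pathway	G6pc	Pck1	Gapdh	Aldob	Ppargc1b
R8	cholesterol biosynthetic pathway	Hmgcr	Hmgcs1	Hmgcs2
R17	vascular endothelial growth factor signaling pathway	Src	Pik3c2a	Apln
R21	coagulation cascade pathway	Fga	Kng1	Serpina7
R28	glycolysis pathway	Hk2	Pklr	Gapdh	Gck	Gckr	Eno2	Phka1	Pygm	Ppp1r3a	Akr1b1
R30	amyotrophic lateral sclerosis disease pathway	Casp12	Txnip	Isg15	Kcnj11	Pfas
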