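gene_symbol	gene_name	ratio
Cpt1a	carnitine palmitoyltransferase 1a, liver	2.2353
G6pc	glucose-6-phosphatase, catalytic subunit	2.3547
Txnip	thioredoxin interacting protein	2.1232
Hmgcr	3-hydroxy-3-methylglutaryl-CoA reductase	2.0119
Src	SRC proto-oncogene, non-receptor tyrosine kinase	2.102
Pfas	phosphoribosylformylglycinamidine synthase	2.524
Ppargc1b	peroxisome proliferator-activated receptor gamma, coactivator 1 beta	2.6752
Ccl2	chemokine (C-C motif) ligand 2	0.3036
Serpina7	serpin peptidase inhibitor, clade A, member 7	0.3717
Fga	fibrinogen alpha chain	0.3675
Pik3c2a	phosphatidylinositol-4-phosphate 3-kinase, catalytic subunit type 2 alpha	0.452
Isg15	ISG15 ubiquitin-like modifier	0.2822
Gck	glucokinase	0.3975
Casp12	caspase 12	0.4165
Cxcl10	chemokine (C-X-C motif) ligand 10	0.4329
Apln	apelin	0.4918
Kng1	kininogen 1	0.4918
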