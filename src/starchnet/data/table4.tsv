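gene_symbol	gene_name
Kcnj11	potassium inwardly rectifying channel, subfamily J, member 11
Hnf4a	hepatocyte nuclear factor 4, alpha
Hmgcs1	3-hydroxy-3-methylglutaryl-CoA synthase 1 (soluble)
Cptla	carnitine palmitoyltransferase 1a, liver
Hmgcs2	3-hydroxy-3-methylglutaryl-CoA synthase 2 (mitochondrial)
Hmgcr	3-hydroxy-3-methylglutaryl-CoA reductase
Bdh1	3-hydroxybutyrate dehydrogenase, type 1
Acaa1a	acetyl-CoA acyltransferase 1
Adipoq	adiponectin, C1Q and collagen domain containing
Pparg	peroxisome proliferator-activated receptor gamma
Ppard	peroxisome proliferator-activated receptor delta
Acsl6	acyl-CoA synthetase long-chain family member 6
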