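gene_symbol	gene_name
Phka1	phosphorylase kinase, alpha 1
Hk2	hexokinase 2
Gckr	glucokinase (hexokinase 4) regulator
Gck	glucokinase
Aldob	aldolase B, fructose-bisphosphate
G6pc	glucose-6-phosphatase, catalytic subunit
Pygm	phosphorylase, glycogen, muscle
Ppp1r3a	protein phosphatase 1, regulatory subunit 3A
Gapdh	glyceraldehyde-3-phosphate dehydrogenase
Akr1b1	aldo-keto reductase family 1, member B1
Pklr	pyruvate kinase, liver and RBC
Eno2	enolase 2, gamma, neuronal
Pck1	phosphoenolpyruvate carboxykinase 1 (soluble)
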