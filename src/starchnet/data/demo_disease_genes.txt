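Cpt1a
G6pc
Txnip
Hmgcr
Src
Pfas
Ppargc1b
Ccl2
Serpina7
Fga
Pik3c2a
Isg15
Gck
Casp12
Cxcl10
Apln
Kng1
Foxa1
Igfbp1
Hnf4a
Hadh
Adipoq
Pparg
Kcnj11
Aldob
Pck1
Hk2
Pklr
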