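>tdi-miR2118a MIMATSYN0000001 Triticum dicoccoides miR2118a (synthetic)
GUUUGUUCCGAGGCCUUCUCU
>tdi-miR2118b MIMATSYN0000002 Triticum dicoccoides miR2118b (synthetic)
GGAAUCAUAGAUCAUCAAGAG
>tdi-miR2118c MIMATSYN0000003 Triticum dicoccoides miR2118c (synthetic)
CGGACCCUAUGUAAAUCACCA
>tdi-miR2118d MIMATSYN0000004 Triticum dicoccoides miR2118d (synthetic)
CCAAGGCGUCACUUGAUAGCA
>tdi-miR2118e MIMATSYN0000005 Triticum dicoccoides miR2118e (synthetic)
CCUGAAGCGUCGGUCAGGAAG
>tdi-miR167a MIMATSYN0000006 Triticum dicoccoides miR167a (synthetic)
AUUUGUCUGGCCUACCUGGCG
>tdi-miR167b MIMATSYN0000007 Triticum dicoccoides miR167b (synthetic)
AUAGUGGGCGAGCCUAUUGUA
>tdi-miR169a MIMATSYN0000008 Triticum dicoccoides miR169a (synthetic)
AUACCCGAAUAACCGUUGGUC
>tdi-miR169b MIMATSYN0000009 Triticum dicoccoides miR169b (synthetic)
CUCGAAUCGGCGGCGUUUUUA
>tdi-miR399a MIMATSYN0000010 Triticum dicoccoides miR399a (synthetic)
CGCACGGAGCAGUAUACCUCA
>tdi-miR399b MIMATSYN0000011 Triticum dicoccoides miR399b (synthetic)
GCCAUUUGUGGACCUUUGGUU
>tdi-miR156a MIMATSYN0000012 Triticum dicoccoides miR156a (synthetic)
CGGUGGAGCCACAGUGUACUU
>tdi-miR164a MIMATSYN0000013 Triticum dicoccoides miR164a (synthetic)
AAGAAGAAGUGAAUCGUUGGU
>tdi-miR5048a MIMATSYN0000014 Triticum dicoccoides miR5048a (synthetic)
CCGCACAUGUCAGAGCUGCAU
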