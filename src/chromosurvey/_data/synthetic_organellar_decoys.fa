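>chloroplast_decoy kind=chloroplast synthetic decoy sequence
TAGAGTCAGATACGATAGATTACCCTAGAAGTTTTACGCAGGTTGCAGTGGACTTGCCCTTCAGTTCACC
AAATGTGAAAGAATCGGATCCTAAGAATAAAGATGAAAAGCGATAATAGCAACACTACCAAAATTGGGTC
GTTGCTAATGACATACTAGTTTAGCAGATACTTTCTGCATTTCGTACGTAACAAGGTATTTAGGAGGTTG
CGAATATATTATGTTAGTAGAAATAATTGAGTATAAGCATATTTTGAGGCTCTTTTAGGTAAATTTAATT
TAGCACATTTATGTATGTAAACGTACAACCTGAGAATAAATGTTCCTCCAAAGTGACACAGTGATGATTA
AACCTACAAAACCAGATCCGTGTACGTTGCTCGGCAATTTCACTATGGAAAGCAACAAGTATATTTACGA
TATGAGAGTCGCTCATATTGTACGAATGTCGATAGCACTGAGCACGCCATGTCCCCAGTTTTTTTTTTGT
CCGACAGAACTTAAGCACTGAAATTGTGTATAATAATTTTGCTAAGAGTTTCAAGAACGCACTAATCTGA
CACAGACTTAATGCCCAGGCCTATGAACCGTAAAGATCGACGTTTCAGACTCTGGTAACAATTCTTAAGA
GTTTGTTAAAATTAGTCGACTTAAGATGCTGTTGTGGTCTAAGGTAATCCGACTTCATCCTAGAGTAGCA
TACGTCTTAGCCTAATTCAGGCTACTAAAGCTACCTGAAGATAATCAATATTTAGATTATTTACTTAGAC
TAAATTTGGGTTTAAAGTCAGCTGCTTGTTAGATTAGAGTATTGTGTGTATAATCATTTCAAGTCGCTTT
CTCAATCTAAGTGAGAATTGGATGGGATTCGTTTGGCGATGTTTTCCCTCAAGAACAATTTTTCATAATC
ACGTGCTCCTAGCCACAAATCACTTGAAAGTGAAGACCAAGTGATGCACGTTCGGTAGGTATGTGTATTG
ACTTATACAACAGTACAATTTATAGCTCATAGGAAACTGAAGTACGTAAAGTTTACATCTACTAATGTTC
GGTGGCTTTAAAAGGTGAGTCCCATGGTTCTTTAGAGCTGTGGAAGACGAGCCCTGTGAGGAGTATCCGT
ATGTCCTAATCTCCTGTCGTCTAAACCTTAATGTTGTGATACGGCTTTTGTGCGTGATTAAACTATAAGA
TATTGGATATCTATCAGATAAGCGCGCGTCCATTCTGAAATGCTTCTATTTTCCTTTAGTTTCCAACCTA
CGCAATCACTTTTTCCGTACAGATTCCAACGTTGCTTGATAGTGATAGATGAATTGTTATCTTAGTAAAA
ACCCCGATACCAGTAGACCTCGTCACGTAAGCGGTAATGTATTGGAAATGATTTGGTCCCGCATGTAGCA
CTATGGCCGAAAAATCAGGCAAAAAACTGCTTTTTGTCTTAGTATGAAGTAACAGAAATACGACTATTAG
AGTTCAATCACATCAAGCGTTCTCTGGCATCATCAAATATGTTATAATAATAATACAAGTTTTGTAGTGA
TTTTTCTGGGTTTATAAATTAGTGGAAGGACAAACGTGACAATTCATTTATGTTGTTCACTTAGGTTGCC
TTTGTCGTATGTTAAGACAGTCTCTTTATGTCTACATATTGCCGCGAAGAGATTTTATGTCTAAAGTGCT
CCATTACTCGTAAATAACTATGAGCTAAACCACTCGCATCCAGCGATCGCTTGGCTCGACCGGAGTTTCT
ACTACGCTATTTGTGGTGATAGCATGCGAGGTAAAGACAGTCTTGGTCACTTTATACTATGAATATTGTC
TGTTTACTACTGCATAGTGTAATTCTAAGGTACTGACATACTCTGTGTAATCTCTAATCGACGCAATGAG
TAAAACCAATGGCTTGAAAGAGCAATCGCTGAAAGTTGTATTAACTCTCATTCGCTATTTTTAGAGTGGG
TTTAGTACTAAGCATCTGTGCCCCTCGTTGTCCGTCAAGT
>mitochondrion_decoy kind=mitochondrion synthetic decoy sequence
TATTAACATTGACACCTGCTCATTGCGAACAAATGTGAGCCGAATCCATTCTAAATTACGGCTCGAAGGT
AGTGGATCTGTGTCCACGCTGGCTTATCATGGGTACCCCTACCTAAATTAACTTCGGGTGTAAGCTCCAT
TTAACGGGTGAGATTGATAGCCGGATGAAAATCGTGCGGAGATAAAAAAGCGAAAGTGCTTGTATTGGGG
TTCTTGAGAAGTGTGTTATTAAATAAGGAATGTCAATAAGGTTTCGACAATGTGCTGTAACTATCGTATC
GCGGCTTAATATCAAGTTCGACTTACATTTGAAGCGAAGACATTTGAGTAATCAAACTTAGGAGTCGTGT
TCCTCCTACTTATCAGATCGGGCAGGCCTATGGAGCTCTAATAATTTCGTCTAGACGTGCACAACTTCCC
TTGCTTACGGTTTGGGTTACCAGTGATATGGCGGAGCCCTTTGCGCTGAAATAAATCCCAAAGCCGGATC
GGAAGCAATTACACCAGTCACAATATCAAGATCGTACAAGTTCGGAGTTCTACATTAAAGTAACAACTAA
ATTGTATGTGTCCAAAAACTCCTCAAATAAACCCGGTAATGTATGCTGTATCAACACGCCGCCATACGTC
CTCAACCAATATCTTGGTCACTATATTCCGCTTTTTTGACTAAACTTACTGGTTTTAAGGAAAATACAAT
GCTGTATAGGACAATTGGATTTCCGCCACAACGCGGGGAATATTGGCCGAGGGAAGTAATAGTGTCGAGG
CAATCGCGGCTACTAATTTGCGAGAATAAATAGGCAAATAGTATTTGAGACTAAGACGTATTACCTGATG
TCGGTGCGGTTACTATCCAATAACACCTTTGGATCCCTTGTGCGTGTGTGAGTTTTTCAGGTACAATCCA
ACTGCAATTTTTGAAGCAACACAACTTTAATGAGTTTACCATTTGAGACCGCAATAATTACGAAACCAGC
CGAAAATGATCAGGACTTCCCCCAGATACAACTAAAAGACGTTTGAGAGTGATTCCGTTTTTCATAGCTT
ATCGTACGGACTATCCCAGGTTCAATGTTGAATGATTTGATTCTAGTACTTTTTACTATCCATTCATATA
ACGGACCAGATTATTTTCAGACATCGCTGGCTCGCTCAGGGTTAGGTATTCTTTACCGTTTATATTTACC
CTGGCTGGAGCTGAATTTGATTACCTACCAAGGGCGACCTATTGCTCATGCCGGAAAGTCATCGGTGTCT
CGTCGTCTTCGGCTACTCGTGTGTCTAACTGGTAAATGGTAGAAGTCCGCTATATATGGGCTGTAAACGA
AATAGCCATATTTGAGATCGTTCACAATCATATAAACACCCTTTGTCTGTGCACCAGCCCCCATATCGGG
ACTTTGTCTATGTGTGTTCAGCTAAGCTAAGCGAGAGGTTCTAAAGAGATAACCTATAAGAGTTTTTGGC
CTGTGCGTTGTGACATTCGTTCAACTTTACCAAGGGTCACTAGACATCACAATAAGTTATCAAACCAGGG
TCATATTCTTCTCGGTTATTCAAGGGCCTCGTCGCCAAGGTAATTTCCACATACGCAACACACTGGTCCA
GAGACTATTCCAACTATCATGGAGGTGGGGAGAATTCTTAACTTCTAGTGGATGAGAGCTGTTAAATCGG
GTGTCACATGGCAACCTCTTGCTCGCTTTTCAGCCATAATCTTCCCGCATCGAGTAGTGATCATCTCCAT
ATGGACTCTGGTTGATTGTCCGATGCTTAAGAGCATCCTCGACTAATATTTTGGTCGTCCCACTTCACGG
ACTGTGAGGTTATGGAGGCCAACCGGATCGACGGATTGACACTGTGCCTTCCTAAGCCTAAATCCATGAT
CTCCTGCCCCCACGCCATCACGATTTGGTGTGTTCGCGAAAGAAGATGAAAGGTTCATCAAGGGACGTAG
TGCAATATAGGGGGACCTATTCCACCTGAACGGTTGTCCT
>rrna_decoy kind=rRNA synthetic decoy sequence
CTGTCAATCCTTCAACTGAAGCTCAGGTGCGAGGCCTTGTTCGAGAGTCACGGGCGCGCAAGGCTTCGGC
AATGCACCGGGGCGAGTGAGCGTGAAGCTGAAGCACGGCGCCCGTCTCGTACCACTCTCAACAGTGGTAC
CAGACTGCTCCCAGCCATATTTAAGACCCCTTGTGCCCTGGATCGGCCGCACGTTGCAAGCTGCTATTGG
CAGCTGGCATCTGCACCATGAACTCTCTCGCTTGTCTTAATAAAGCAGACGCACGTATGCGCCGGTAGCA
ACTTATGGTGACCTACTGGGTGATACGCCAAGTACCAGAAATGGGGTCGTGTGACCAGTAAACTGATGAG
CTTCCGACCATGGCTATTTAACGTTTGGCCGACCTGGGAGCAAGTAGGCGCCACGTTTGCGCTAATCGTT
CCCGACAGGGGCTACGTTTGGCCGGCTGCGATTGTAGCCGGGGCAAGACTGTCGAACATGGATCGCATAC
GGCCCCCAGGCGATAGTCCAGGGTCCAAGCGAGAAACAAGCGGCACCGACCTACAGGATCTCAACGTGGC
GGTAACCCCACCGCCTCGCTCCAGGCCCAGTATACCGTTAGTCAAGTTGACTTGCGCTCACGGGATGTGA
TCTCCGCACTGCACACCCTCTAAGTCGTGTCGACGCTGTGCAGTATTCTTATTTGCTATTATGGGTTTAG
CTGATAGGTTCATGCCCTTCTAAAGGAAGGTTCATAGGCAAGATTTGATCAAAATAGGGGCGAGAGTGCA
AGTTACCGCTTAGCGCGCATGACCATGACCGACCGGTACTTCGATCGTCGGATTTTACGTGATACTAAGC
GGATCTACCCCACCGGTCAGACATACAACTTTACGTGTATGCAGCAGTCTTAAACATCCGAAACTCATGT
TCGCTGACACTTGCCACGAAGCACAATTGACGGGACTCCTTCAAGTTTTCTAGCCTGAGGCCGCCGGGCG
ATTGCGTGCGACCATAGACCGGCTTCACGTGTGCAATAACCGTAGATCGGACGGCGGCAATTAGCTGAGG
AGCCGATGCTTGATATGTAATTTACCAACGTCCTTGTGGCATCAGGAGGAGGGGCTGCGCAGAGCCCGTA
GCGGGCTTTCACCTGTCTTCGTATTCAATGGGAGCGGGAACATACGAATTTGCAAATAACAGTTTCCGTC
CGGAGTGGAGCACGAATTTTGAGTTAACTCATCGCGAGCAGTAGGTTCTGCAGTTCTAAGTCTCTTTATA
CGGGATGATCAGTTTAACGAGCCTACTTCCGACCCTGCGAGGGTATGGTACAAACAGAGTCAACACAGTA
TCGTATAGCCGGGCGCATAGTGGCGTAGGCACGGATGCAGGTTAATACAGTGATGACCACCAGTTACGGA
AACGGTTTCACGCTGAGTCGCCTTGACCTATCGCTGTTCAGAGAGGTGTCACATATCATCTCCGGGCGGT
GGGAGGCGATCCACCGTATCTCCACCTGCCTCGGCTGACCCCCGTGTGCCAACAGTGATCTTCGAACCAC
AAACCGGCCGAGACCCCGGGCTGATTTGTCACCTAACGTCCGACATTCGTAGCGCCGCCCCGTCACCGAC
CCATGTATTCGCAGGTCTAGAGTCTGGCTTACTCACACTCTCTTAAGGTATATGGGCATGGGCCTTTTTC
ATTCTGTTCGCACCTGGCCCTGGTGCGGGGATCCCGCATATGCGTCCACTCCGTGTCAGCTGAATGTCGT
ATACAATCACACTGCCTACACACTAGACAGGGTGGTGGAACCTGCCCACT
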