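>YDR382W_synthetic
ATGGACTTGGTCGAACAATTATTAGAATTGTTTGGCGAATTTACCCCGGAAAGATTTTTT
GAAAAACAATATGAAGATGGCAAGGAATTGGTCTCTGAAAAGTATTCTGAATTAGCTCGT
GAAACCAAGATTGAACAAAACAATGAATTGGGCTTAGAATTTTTCCACGAAGTTTTTAAG
GAACAAAAAAAAGAACAAGGTAAAGGTGAAGAAGAAGAACATGGTGAAGAAGAAGAAACC
TATGATAAGTTGGGCTTCAACGCTACCATCTTCAAATTACGTTTCTTTTGGCAAGACGCC
GGTGTTACTCAAAATTTACCAGCCGTTACCTAA
>YLR378C_synthetic
ATGTACATTTTAGACTTCTACGAAGTCCAATATGGCGTCGAACCGGTTGATCCGGACTAC
TCTTACAACACTAATAAGTATAACCAACGGAATGTTACCGGTTATAACTTATATGATTTC
AAAAATTGGTTCATTAAAGTTGATAAGTATAACTCCCCGAAATGGAATGTCGGTGTTGGC
CACAGATTGTACTGGTTTGTCTATATCCGGGAATTGTTACCGAAGGACTACTTGGAATTT
AGAACCTACGAAAACGGCGCCATTGATCCATGGCCGTGGTTGAAGAAGTGGTTCGACTCC
TCCGGCTATTCCTTTGCCCCGGTCAAGCGGAAGTATGAACAAGCTTATAAGGTTTTCAAA
CGCAACTACCATAGACACGTCGCCGCTATTGCTATCATTGGTAAATCTAGATTGCGAGCT
TGGACCACCGCCGGTTTGTTAAGAACTCGGGAAGACTACACCAAGACCTTCAGAGTTTAC
AAGAACGGCCATCAATACCACGAAGATCAAAAGTTATTCCAATTGGAATCTAGATGGATT
TTACAATGGAATATCAAAACCTACGTCCGGGATTCCAGATTGGGCAAGGTCGTTGGCGTC
GGCTGGTTGTCTGGCGGCCATGTCAGACCGCATACTCAACAAGTCTACGATTTGTTGAAG
AAGAAGCAAAAAGATCACGAACAAAATCGGGAACAAATTAATGCTGGCTTGTCTAGACCA
ACTGAATTGGAACGAAAATTGTTAACTTTCGGCGCTACTCACGGCGGCACTTCTTACTTA
TATGAAGGCGACGAAGTCAAAATTATCCGGGACCCGAATGCCTTAAACTCTGATATTGTC
GCCTATTTGCAAATTGGCATCATCTTAAATTTGATCTTAAAAAACAAACGATCTTTGAAT
CACTTGCATAACCCAGTTAAGGATCATCGGGAATTGCATCGATTGTGGATCAAACGACAT
TGGGCCAAGGGTGTTAATCACATCAAGAAAGGCTACTCTCAAATTGAAACCTCTAACGAC
TCCTCCGAACGTTTCAATGCTTTAAGACGGAATGAAAATATTAATGAATATGGCCCAGGT
AAGCCAAAGTGGAATACCGACAGACCGTTCGGTGTTAAATATGCCGGCTTCATTTACCGA
TTGAACGACGAATCTCAATCTGGCTTTCGGGTCGTTTTGGGCAGAGAATACGTTAGAGGT
CACATCCGCTTATCCGCCTTATGGTATATTATTCCATCTGATACCGCCCCGTTAAACGGT
GAAGCTCAAAAAGATCACTCTTATCAACGGAAGCCGAGATCCAGAGTTTTGCATAACTTA
AAACGTGGCATTGATAATGTTATTGAATTGAAGGGTGAATACGATAATAGAGCCAAGACT
ATCGGTGCCCCAGGTAAGGAATCCGCCCGGACCAAAAAAGAAGACTATGACTATACCAGA
TAA
>YJL136C_synthetic
ATGGGCTATGTTGAATCCCAATTCTTAGAATCTGATAATCATGAAGACGGCGCTGATGAA
ATTTCCAAAGACGAAGCCGCTTTCAAGGAAATCAGACACTTTGAAGCCAAGGGTAATGAA
TTGACTCCAAACGAAATTACCTTATCTTTGTTTCACGATTTGCCGGAAGAAGAATTTGAA
GAACCAAAATATGTTATTAAGTACAAGGCTTCCTCCAAATATTTGGTCCAAGACAAATAC
TTGTCCCAAAAATTTTTACAATAA
>YMR307W_synthetic
ATGGTCATCTTAAAGGCTGTCGATTGGATCATTATTTCTAAGCGAGGTGATTTGCCAGCT
TTTTGGGCCGCCCGGTTCTTGCAATCTTACACCTTGCCACAAGTCAAAAGAACTAAATTT
AGAATTAAAGAAAGATATATTTTTGTCTACGGCGCCGAATTAGGTGGCGGTAAAAAGCGG
AGACCACAAGTTTTTAAGGCTCAAGAAAATAGAGCTTGGGAATACCGACATTGGGGCGGT
GGTAGAGTTGTTTGGGAAAACTCTTCCTTGTTCGGCGGTTTAACTGCCCATGATGGCGGG
TGGCAAAGAGACTATGATGCTGTTGAAGTTGTTAAGATCACCGATCGTCACGATCATATT
ATCCCAACTGATTTCTATCCGCCGGTTTTGTCCTGGTTAATCCCGTTGTTTACTTGGGAA
GCCCCAGAAAGAGGGGACAATCAAGGTGGTAAGTACATTGGTATTCATAAGGACGAAAAA
TCCCCAATTTACTGGGAAGCCGATTTCGATGTCCGAGAATTTCCAAAAGATAAGGCCTGG
GGTGTTGCTGTCGCTAAAACCCCGTTGGGGGAAAAAGGTGCTGCTGTCGTTAAGAAAAAG
TACGCCGACGACAGAGACGATTCTGAACAATTGCACGGTAAAATTTCTGTCTCCAAGGGC
GTCCAATTCGCCAGAAACGGCAAGAAGGCCTCTGTTGTTATCGGGAAAGCTTTGAGATAT
AAGTCTCACCCGCCAGTCTCTGGCAAGAAGGGTGTTGACCGCCGAGTCCCGAAGGCTAAA
GTCGGTTTCAGATTAGTCTCCAAGGCTTTGCCGTCTTCCTGGCCGGATGTCATTTTTGGG
CACACTGACTTCAAGCCGCAAATCGGTCATAAAGCTACTGAAGACGTTTATCGATCCTGG
TTCGACGAACATCCAGACGAACCGAGAACCGCCATTGACGTTTTGTACGCTTTCCACCCA
AAAGCCGACAAGGGGGTCTTATACACCGAAGACAACTTAAAATTAGCCGACAAGTCTTCC
ATCTTCATCTTATTCACTTTAGACCCACCGTCTGTTAGACAATTATTCTTCTCTGAATTG
GAATCCGATGAAAAAGCCTTAGATACTGGGTTTTCTAAGCAAAGAGTCCAAGACGAAGTT
GTTGGTGGCAAAAGACCGATCAAAAAGGACTACGACTACTACATCCCGAAGTTTGACAAG
AGACAAATTCGCGGTCAAGTCAAGTCCTTATCCTGGGAAGTTGGGGCCGAAAGATATTGG
TTGTTGGCTCAAGAAACTTGGGACAGAGATCGACATGGTGGCTTGGGTGAAAAGTTTGCT
AAGTATGAAAATGGTTTATTTGACAGAAACGCCATTCGAAGAGCTGACAAGACCCCAGGG
GGCTCTGTCGTCGGCGATATCCGTAACATTATCATTGATTTGATTAAGGTCGTTCCGTTC
AGATCTGGTGCCCCGCATGAACCAAATAAAGTCATTGGTAGAGGTAGACCAGACAACGGG
AATGAACCGCAATTAGCTGACTTGTGGGGGCGAGAAATCAAGTGGAAATTTTTGAACGGG
GGGGGGGGGATTTCTCGATATAGAGTTACCGGTAGAGAAGCCCCAGACAGAGCTGGTGGC
TCTTCTGGCAATAACGAATTCGAACGAACTTTGGAATCCAAGGTTTTTATCGATAAGGCC
TAA
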