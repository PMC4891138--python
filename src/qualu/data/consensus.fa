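>AluY_like synthetic 288 bp Alu consensus carrying the AACCCGG anchor (assay target)
GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACGAGGTCAGGAG
ATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAAAAATACAAAAAATTAGCCGGGCGTGGTGGC
GGGCGCCTGTAGTCCCAGCTACTCGGGAGGCTGAGGCAGGAGAATGGCGTGAACCCGGGAGGCGGAGCTTGCAGT
GAGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCCGTCTCAAAAAAA
>L1PA_like synthetic 600 bp LINE-1 segment, free of CCGG (digestion-independent normalizer)
TGTCTGGAATACCAGTCGTTACATCTCAATTGTGCAGTCTAGAAAAATAGTCACACTCTTGGAAAGATTTGGTGA
AGTATCCTATAGTTATATAAATCTGTTACCTAGACACGGTGACAATATTGCCTTCTTTTAATTTGATTGTCATAA
CCTTACAATGTGCGCTGTCACAACTAGGTTGAGTCTAAAGCACTTGAAGGCGTTTAAGTTTAGTATATTGCCGAT
TACTGAAGACGGCAAATATACATCGATACAAGATGTAATCACACCATTTACAAAAGACCGTGTACGCAACTCTTG
TTAAAGACAGTGATTACTTAAGATAGCATACCCCAATGTGTACAAGTAAAACTTAAAAACTTTTGGCAACTAACG
AATTATTACAACAACGCACACCACAAGCTAAGCCAAGCCTATCCTTCAAATATGTAAATTACCACTCTCTTTTAT
TCCTGCATGTAGAATGAATTAAGACGATAAGCGTTAGCGGAGGTTCCATAACTGGAAGCAGGCAGATCCCCAATT
ACGAAATTAAACGATATCACTCGCCCTTGGTATAAAGTTACTAGCGCTCTTTAGATTGTGTTTTTAATTAAATTA
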