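>amplicon demo_locus 2000bp
GGAGTTTCCATCCCGTCAGCAAGGACAGTTTGTTTGACACCGAGCTTGACCTTGGACCTTAAAGGCTCTG
CGTGGTAGATCTAAGTGAACGGTCTTGCCCGGGGTAGGCAGAAACGGGACCAACTGACTAAGTGACGATG
CACCGCGTACGGGCTATGACGGAAAGCCTTACTTAGGGCATTCGGCGTACCGTGTGACTTCGTAAACGTT
ACGGCGTAAGTCACGACCCGTATTAGTCACGGACAGCGGTGCTGTCGAAATTGGCGGAAAACAGAGGCAC
CTTCCGAAAAGCGCCCCTCACTTCGTAGTTGTCGGATTTAGCTCCAGAACAGGGCTCCCCCTCAAAAAGG
TTGGCCACGATAGGATAAATTCCCGCTAGCTGACTGGAAAGCTCACGGGGGCCTACCCAATATGTACGTA
CACAGAATCACACGACGTGAGCTAGCCGACGTGGGTTACCTGCCGCGAAGAATCGGCAGGCTCGTGCAGT
CAGTACTGCTATGGAGGAAGCTGAAAGAGCAGTTGATATTGATCGAGGTTGAGCCTACCTTTTTTCCTTC
AGCGAAAGCATAAACGATGAGCGTCGTCCCCCGACTTATAACTGCATTGTGAGTTTAATAGAGCACCGTT
GAACCGAAGGGTCCATACGTGAGGCTCAGATCGCTCGCTGTGGCTATGAGCGAGGATAAGAGCGTTAGCA
AAGCACATGGAGCTTGGTTGATTTCCTTACCCGCACAATGCGTAGAGTGCATCGTCTCTTCTCTTCGTTC
ACTGCGTACCCCTTGTCTAAGGATGCTAACATTGCAACCTCCTCATAACGGAACTAAAGCTATAGAAAAG
GTGACTCGATCCGCGGCAGTTCACATAACCCCACGAGAACACCACTGCGTCTCCAGAGCTTTAGACTGAT
ACTAGGGAATAAAAATATGGAGTACTCAGTATCCCCATATACGGTCATCACGTGATAGATCCCACGCTGT
GCGATCAAGTAACAGTGTAAGAGGGAAAATGGGCGACCCCTGACAGCTTATCTAATCATGTCTTATGTTG
CTAAACAGGCATCATATGGATTCCGAAATATAGCCATCCATTCCCCTTCGATAACTATCCTCGATTTATT
GACGTCCAGGAGGCATGTTAAAGGCAGCACCGTGCCCATGACTCTTTACGACGAATGAGGAAAAGAAGTT
AGCTCAAGCAGACTGAATGCAGCGCCAAAGGATTGGCCATTAACGGACGGCGTGCATTAGCCTAACAGCC
TGGAGCGACGTTTGCGTCCCTTATACCTCGAGAACGGCGGAGCTGCCTGGAGGAAAACTAGATGGTTTCT
AGCGCAGTGTGGAGAGATTATTTCCGTCGGTAACGTGATCCCTATCATTAAGCAGATCCCAGCTCCAACG
TGCGTGCCTATCCCCCCAATGAGTTGTTGCCTCTCGCTACGCTACTGGCCTCATCTTTATCGATATTTCT
CGTATTCAGTTTCGATCCCACAACGGATATAGCTATTCCTGACGTTGATTACTGCCTCATCTCCGCGTGT
ATTACTTCACCGGCGGGCTTCGGCAACGGCAGTTCGTACAGTACAATATCTGAGTATACCGGCAGTACGG
TGCGCAGGGTTAAATGATAGACGGGCGATAGCGGTGTGCATAGCCATGTTCTTTCCGCCGGGTACGATTC
GTGTAAGGGAGTGCATCTCAACGACCCTAAGAAATTCCAAGCCCCTGCAAACCGGTCTGAGCGACACTCG
GTTATCTATACCATAAAGCCTCGGCGCGGCCTTTTGCTTTATAATTTTCGTCGCTTTAATTAGGCCGTGG
ACGGCTACTAGACGACGTACGTGTCTCTGAGCGTTGATGCGCGGACGTATTCCTCTCTGGTTTCCAGACT
TCGGCAGCATCTATACCTCCCTTCCGGACACCCGCCTGCGTCCCCGGGAGATGTCCTAGCCCAGACCCAT
TTACATCGGTACCTATTACCTATGATAAGAAGGATCACGG
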