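>TOYHV1 synthetic
AACAGATCTGCGAAGAAGCAAGCCAGGACGTGTGGGTAGGTTTTGAGTTTGTTCTTTGCC
GAAGAACCATGGCGGCCGACGCACGTA............CATTCAAGTTCCGTTTCGCGA
ACTCTGGAATTTTCAAATGATACGCTCTCAAGCGAGGATTGCACAATTGAGGGA......
CTCCGTGCCCGAGGTGGTGTGGGGTGGTTGTGTCACTTAGGGCGTATGCATGTCCTTTAT
GTATTACTGGCTTTGCCAACTAGGATGGGGCGGGAACAGTGTACTCATGGAGGCTATTAG
>TOYHV2 synthetic
CGTTTGAACATAAACTCAGACCGTTGCATACCCAGGATGAGTGATACTCCGTTCAACCAA
GTCGCCCTGGTGAAGAAGTCGTAATTGCCTGCAAGCCGTTATTACTTGCTGCAAGTGTAA
GTGGTCCAATTCTAAGTCCATCTCTTAGGGACCTTACAATGTGCCCCGGATATGGCTGTA
AGGAAAGTTCAGCCATCCAACTACCGCAACAACCCCCGCCATCGTGGAAGTTGTACCGTG
ATGAATGTACTTAGCAGGAAGCTCCTCGCCCCCCATCATAGCTGCCATTTGCCCCGATGT
>TOYHV3 synthetic
CTCCAAATGCAAGAAGTTTAGTTGTATACTCTCAGATAAACGCGAGGTGCCTCACCAGGA
TCGACTCGTTGTTCATCTTCAATAGCA............GACACTGAGTTAGCCTTGTGA
GGATACACCTTGGGTCGCACCGTTACGCATCAATAACCGCTGTCGGCCGTGCA.......
..GGATCGTAACGAGCTGGCCGGTGGCGGCACGCGTCGGCCAATAACGGTAAGCCGCACT
ACGCACCATTGTCCTTTGCGTTGCCACACTGAATCTAATCACGGCATCGCATGCTCACGC
>TOYHV4 synthetic
CTTTGTATAGACATACTACATGAGATGCCCTGTCTTTCAAAGAGGACTGCCAGGGAGAAA
CGATCGATGAGCGTAGGGCTCGGAAAATCT......TACGTATGTGGTTGTAAAGATATG
GCATAGCCCCGGCTGCAAGTGGTCGGGCATTTCGTCGGGAGTTCATAAGGCACA......
ACCGTGTAGTAGTCCTCCGATTTCCTGCAGGACAGTGAGAGCTCACCCAGTCAATTCTCA
AAACATCGGAGATCAAGTCGGGGTTGTATTTATCGGGCAGGCAAGCGAGGACGTCTTCTT
>TOYHV5 synthetic
TGCCTATAGATGTGGGGCTCCACCACAAAACCGTGCGCGTACTATCAGGATGTGTTTGAT
AGTACGTGCGACACTTCCTTCAGGATA............AGTGCTCCTGGAGTGTCATAA
GTCCTGGTTGATCCGGCTGGTCCCATGATGCGGTTCCTCAGGGCTCAACTTTTACCATCT
TTCGTACCAGCCCATTTTTAGTTAGTTAGGCGTATAGTATGCATGGTCTATAACGTACTT
TGATTTTAGAATGTGGCTGATTAATTACACGGAGTCGGGCCGATTAACGAACCATCCAAC
>TOYHV6 synthetic
TTCGCTTCAGTTCTTGCGTATTATCACCCCCAGGTACCAAGACGAGCCGCAAGCCACTAT
CTCATAAGAACGCTTTATCGTCAGGCGTACCAGCCGTATCTCGCCTACCGAATGGTAGCA
CACTGCAAATCGATGATTTCGGAGGTTTCGGCCATAGGTGACCCCGGCGATTA.......
..TCTGCAGCGACTTAGATGCGTCCGATGGTCCGTTAGGCGTTTTCAGATAAGGATGTTC
CTGTCATGGCCTGACGGCCGGGGGGAGAGGAGGTGATGATACACAGCTCGACCAGCACGC
>TOYHJ1 synthetic
GGGCTCAGTTTCACGTATAGCAGATTATACGCTAGGCGATAGGATAGG
>TOYHJ2 synthetic
GCGAGCGATGAGCACAGCCAATCCATTTGGGCAAAGCTTCCGCAGATG
>TOYHJ3 synthetic
GGAGATAGAGTATATCTCGACCAGCGCCCTTAATCGGTCGGAGGTACA
>TOYLV1 synthetic
AGCTTACCCAATCTGGAACATCGGTCACTGGACTAAGGTCTTATGACAGCGGGCCGGATT
CCTGCCCCCAGCCAGAATGTCCAA..................ATAGTGCGCATATGCATA
CATGTGCGCAAGAATCTACCAAAGTTTCGTTAATCCAGATGTGGAGCCGCTCC.......
..GTACAAATAAGAAAGGTAACACAACTGATTTGCTGTCGCCCATCGCGCGGCTACACTT
TTGTCGCTACGGTTCAGTCACGGTCCTAATTAGTAGGATGGCAAATCCCGACTACGTACC
>TOYLV2 synthetic
TGTGATAACGAGCGTATTACTCTGTGTGGACCCCTGGACAGCGTAAACCTGTATCGGTAG
TACACCTTTGGTGAGCGAGAAGGAGTT............AACGCCTCATATCTGGCTCTC
GCCGGATCGAGACTGTATATGTTCTACGCTTCGAGTCATACAACGTTGGAGTG.......
..TGTCGCCTGTACTTTCGCTACACTTCAGATGTCCGGTAAGGAGGTCAGTGCCAATCGT
ACGGCGATACCACAAAATGAACCTGTGTGGCTTTAGCCCAGATAGGTGTAGCATACGGGC
>TOYLV3 synthetic
TGTAAAAGCGTGCACTTACGTTCGACACCGACAATTTTTGGGGATTATCTGTGCGCGGCT
CGAACTACTACCTATGCACGGCGC..................TCCCCGTTGTTAAGTGTC
CGTATCTATATCATTCAAAAATCACGACGTCCGCTAGGCCTAGCAGGTTCAGCGGA...A
ATATGCTGCCCTGTAGTGCGCCGGTCTCACACCACAATGTTGCGGAACTTCCACTGATCT
GAAGCCATTGAGTATTTTGCATCCAGTTTGAGTATATAATATTTCTGGCTCGTAGGAGCA
>TOYLV4 synthetic
AGTTAGGTCCCGTCTGCGTGAGAAGCGCTCATACGTCTGACACCGATACCGTTGCACTAG
CTAACCCAGGATTGGCCAGACGAGTTCGAA......CATTCGTTTATGTCGCAACAATGT
CCGGTGGCTTCAATCTTAACCAGTATGCTTGCTATACGGCCATTGGGTCTACC.......
..CATTTAGTATTTCATCCTTGAGAATCTAAGACCATAAAAAGCGCGTCGAGAGCGCGCC
TCATCTCAGTCGTACCCCTGGACGGTGGGATAGATTTTCCTCAGTAGTTCTCCACAACGG
>TOYLJ1 synthetic
CCAGGCTCGCTTACAGCCAATAGCACCCATGACACTGGATTCCAT
>TOYLJ2 synthetic
TTCCCAGTGATGGGGGCAGGCACTACATGCGCGCTGATTGGAAAG
>TOYLJ3 synthetic
GACGGAACGGGTACCATCGGCTCTACACAACCCTTCGACCGAACT
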