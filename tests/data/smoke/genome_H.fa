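>chr0000
TGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTTTTATCGCAATTCCAATGAAGT
TAGAAACCGCCTGGGCTACAATACTGTACAATAGACCCCATACAATACCAGGTATAAGTT
GACTGAGAGACCTGGCCTTAACCCCTCTGCCCCCCCCCCATGCGGCCTCGAGATCGGCAC
GTTTTTCATCGTTATAAGCGAAGAGAAACAGGGTGGCATTGGCGGCCGTCAAAATAAGGG
GAGATAAACCAAGAGACCTTCCTGCATCACGATCGGTTCAGTTGGGAACTCCTGAGAGTC
TGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACAAGTAGGGGGAT
ACTGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCAT
CAGTAGTATCAAAGTTGTTCACGAGCGTGGGCCTGCATCTCGAAGGGGATCGAAGTAAAG
CTCTAGTGAAGAAGGTCACGCAGTGGGGCAACCGCGGGCCCGAGGAACGCGGGCACCTTA
ACGACCGTCAAGGTATTGTACCTGAGGTGTCTTTTCTGGCGCGAATTAAATCCGGCACTG
CAGATGGGCTACGTAATATGAAAAGACCACGGGTACGACGGACCCCTCGATGCGTGTTTC
TGCCAAATTGCTATTTGAAATATCTGACGGATGAAGAACACGAGGCACCTACGAGACAAT
TATTGAGCCGACTCGAGCGAAAATGCACAGGTTCCCTGCTGGGAGAATAGATAAGTTACA
GCGTTTACCGCCTTGCCCAGGACAATGATTAACCAGGTGTCAGGCGAACTTGCTTGGGTC
CGGGCGTCAGCCTTACGCTCTCTTCCATGTCTGATTGTGGCGAGGCGGAATAAGACTTTC
CTTTGTCTCAGAAACCAAAATACTCCGGACCGCTCCCGCACCCATCGCGGCCGCCTAACA
GAATGGAGATAATTAATGGGGTAAACAACCTTCTTGGTATGCTTACTACGAGCGTGTATG
TTGGGTAGTTCACTCTATCCAGCTTGAGTTCAAAGGCTAGTCGACCGCTCAGACTTTCGA
TCATCAGCGTCCATCACTAATAAGATTTGTAGTTGGAAGTGCGCAGTACACCAGTGTTTT
ATAGTGGGCAGAGTAATTGCTACGACGAACTCGCCGTAACCGGTTAAATAGAAATATAAA
CCGGGCCACACCGAGCCTCGAAGATAGCTCTGAACCTGTGAGGTCACACGGGATCTAGGT
TGAAGGCCACCAAAGTGGCTTCACTACGCTCTATCCCGCATGTATGTGACCCCGACTCAA
TCCTATACCTGTTAGCTGGCGTACTGGGCACTACAAGATCGGTCCTGCATAATCAACCCC
GCCTG
>chr0001
CCATTCGCGGATGTTGTTCTCGTCTATGAGTTACGTCATTATGACCCTTTTGGAAAGACT
TTACTTATCCATGCACCAAAGGTAAGAATGGAGATCAGCTCTGGGGTGGCTAATTCGGAA
GCCAACTGTCGGGAGCGCGGAAGGATCTTACCCCCCCCCATGGTCACCATGATCACAACG
TCACCCAAATCAGACAGTCGGCCGCGACACGGTATCTGCGTGGTTCCCATAAGAGTGAGT
TTAAGTGCACTTTTGTTCGTAGATCGTGTGCTCATACTCTGTTCTTCATATGGGTTGAGC
GTACTCTGATTAGGGCCCTCTCAGACAGAGTTAGCCCTCATACTCACATCCCGCGTTCGA
CAGTGCACTTCTCGCTTCGCAGTAACCATCGTTTTAGCCGATAGGGTACTTTGCTATAGG
GGGAGGATAAAACAGCGCGTCAGAATTATCTCTAGCTGTGAGCGAGTACGAGAGTTTTTC
GAAATTCAATACAGTTATTGAGGAAAGCAATTATCAGACCACCATTAAAGTTTGGCCATT
CAAACTGTGCTCAGTGGCGACGCGCGTCGAGCGCACTTTGCGTGAACACCCTGGGTCGAT
GTTGATGTCGCACAGACTCAGCAAAGCATTACAGGTAGACTGTTCGTCTACTGGGAAGCG
GCATGAGAGCTCTTAGCAGCCACGCTCATCAATCCGGTTCTGACCAAGTAAGGGTAGGGA
CTTCGGGGTGAATTCCCTACGCGGTCGTTCAGGGGTTCACATTGGCTGTCATTTAGGCGT
GTCTGTTATGCTTCCACGTATAATATGGTGTGTCCATCTGCGAAGCCGCTGATTACCAGT
TCGTGCGGCATGTGGTATCACCCTTGGCTCAAGGACTTTGATATGCTAGATACGCACGGC
GCGTACAAGCATGGCCAAGACCTGCCCTTTAGCGTTCTGCCACAAATAATACTACGTCAA
TTATGCCTACCGTGTGCCAACTGCTCCTCGATCCTGCAGAGCGCTCCACTACCCATTTTT
ATTGCCTTAAATGCCCTCACATGTGGAATCCAAGAACCTATTCTGCGTAATGCCACTGGC
CATGCTGTACGCGAAAGAAATGCATGGCCAGCTCTCGAAGGTTAAACGAAGTGAACATGG
CATCCAAGTTGAGAAAACGAGTCTGTCGCTAGACGGCCCCATCAAATTACGAACTCGTAC
CTGCCTATGGGTACAAAGGAGCGGGTTTCACTGCAGCCGTGCCATTAGGGAAGAGGTGTG
GGTGTAACTCGGTGTGGGGTGTTACGGCTACCATATTACATGCTAACAGGTGATGAGCCT
GCTCTACTGCGCTGTTTTCCCGCCGTTTTGATTGCGTACGGCTGCATCGGTGGGAGGGCG
GGTCCAGGGAGTACCCACTAATTTATGGTTTCGCCACCATCGAGGGGGTGACCGGATCGG
CACCATGACAGTGAGCGTGCTTTTGAGATTTCTCGTGAGTCGGGTATGCTGCTACATAAC
TTTATCGCTCCGAGGAATTGACTTAGTAGTAGCCCAAAGAGCCCATGGCAACTCAAGCCG
ATCCAGGGCAGGCCTAGACTAACTGCGATTAGGCGTGGACTGCGTATGGTAGGTCTTTCC
TGCTCGAAAAA
>chr0002
TCATGCTTCATTACGGGATACCCTGAAGCACCTCCGGGGTGTTTCCGGAGAGAGACGTAT
GGTGATAGCCACACGTCCTTGCTGCACTTGGCTTCTAGGTACAACTGGCGTTCCCGGTGG
AAGTAGTTGTACAGACCTGAGTGTCCGTGCCCCCCCCCCATGCGATCGGTACGATTAGTC
GGTATTATGGATGCAGCGGAGCTCCCATTACGTGCCATTCATAAACTACTTGCACCCAAT
TTATTGTCCCGGGCTACGTACATTGGGTTGTGTACGCCGAACTATGGCGTGTGGGGATTC
ATAAGGGCAGCCTGCACGAAGAGTGTACCGGATCTAATACCGGCCGTCCTATGGTGAACC
CGATGGACGGGCGGAAATGGCTAAAGTGCGGGAACGTGAGCGCCGACGGAATGCAAAGAT
AGGACCTATCAGTTTACGATCGGGGTGTCTAGCACCATCCTTCCACGGCCGCCTACGAGA
TCACGGCCCTGCAACGATGTCAAGAAGAACTTTAGCTATCTAGGTCTCAACCGTCGTCAT
ATCCCTTTACTGTCACTGGCACTCAGCCACCAACCCGCCCGGTCTGAAGTTATACGTCAG
GTTAGGTAGTGATCAGACCTCGTCTGGCTGCTTGTCATCTCTAGTGCATGGAATCTTCCG
CGAACTTAACTGGGCATATTTTCCCAGATGCCCTCAAGTTCCCGGTTAGACCCGCAGATG
ACGATGGACCCAGTGCAGTGGACCTCCTTACAGTAACACTATTTCACAGGAACGGTGCCA
GGTGTCGATTTCGGACGAGTGCCCTTCGTACCCTGGCTCAGTTATGGCTTCCGAGTCAGA
GTTACCACGCCTGGAAGCCGTTCGCGGCAGTAGACTTGCTCGGCTACCGCGGCCTATAGC
CGTAAAGTTGTGAACATCAGCGCTAATGAATCGGGCGTGCTATGAGAACGATGTTGGGAA
AGGTGTTTTGCGTTGAGAATCTATATCCGGAGGTCGATTTGCCGACCGTGGTCGAGAGTA
AGTGGACTAGCTTAATACACGATCGGCATGGATGCCATAGCGCTTTCACCTCGGGCTAGG
ACTCATATGCGGAAGAAACATATAGATGGGATTTGGGGTTGTCTCCGATTTCCCCGATGG
TTATGGAGTGGTTGCCATGTAGTTATATAAGAATCCACTTAAAATCGTAGTCCACTGTCT
TTGCAGGGTACTGGGCGACCATGCTCCGATTTGGGGACTTCGTAAAAACTGTGCTTATGT
ATAGAAGGTAGAGATTCGGTTGACGGAGCCACCCAAACCACAGGAGGGATCGACTACGCC
ACTACTCTGTTGCAACTACTAAGGTGAGAAGGGCCGCTTCAGACCTTTCAATGTGCACGG
GTCCGCGGTATCCCAACCGGCTACAGTTGAAACCCTAATTCGGTCCAAAGGCG
>chr0003
AACAACCGCTCCAACGAGGGTTACGCCGGCCGCCTCTGGAGTTGATCTGCAATGGCTATA
GATGCGTCGATCCGCAGGGGTACTTTACACATAGGGAAGCTATCAGAACAACGACGCAAG
ATTGGACATAACCCACTGTGCATGTTACTTCCCCCCCCCATGGTAAGAGAAACTGAACTC
TTATGCCGTCTAGGGGCCGGTCCAATTCAGGGGACATTAAAATTAGCAAGCAGCTCAGAG
GTTGCGAGAGTCCTTATTTTGTGCCTAACCGGAAATGACCTAACGTCGCCCGGAGTGCGT
CTCTGGCTGAAGAGATGAGCTTTTTGCAAGTGTAATATACCGGCCTGTTAAGCGTTGGCG
GAGGGTTTGTGAGCAATAAACGCCGGTACAGTCCCCTTGAAATTGCTAAGTCGAGTCCTT
TTGCCACGCTACAAGGTTTAACCAACGTCTCAAGTGTTAGCGTTTTCTAGTCGTCTTTGA
GGGCAATAGGGCTCTCAACTGGGGTGTGGCAAAAAACACTGCGCGGTTAATGCCCAGCAT
ACGGCCAACTTTATCCCCCGATACGCCCGGGGCTTGTTACTCCTTCGCCGAAAACGTGCT
CACAAGGTTAGCCGTGTTAGTTTCTGGGACAGGTGGGTAATTGTAATCCTTCGCTCCCTG
AACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGCCAGAATTAAACGACTTAGG
TTGCGTCGCGTGACACTGCCGTCCGGTAAATTCTGGCGTGCATTTAGATGTGAGCTTCTA
TAGTCATCCCGGAAGAGCCTTGCTGTGTTGAGGGAGACTCAGAAGTATAGGCGTCGGTCG
GGGCCATTTGCATATCTGCTCCACTGAGCGTAGTAGGCACGGGTGCGACGGTCGGCACCC
ACGCGTATTCCCAGGGAAAACCCAATCTATCCTGCGGCAGAACTAGTAGCCGAGCGTCAA
CAGGATTAACAACCGCGCCGTCTTCATTTTAGACATACTACGATGACCACCCTTGTTGCG
TGCTCAGCCAATGCTTCCCTCTGTCAACTTAGTCTCACATGTGAATCCAACAGCTCCTAA
TCGCAGAACCAACTCCTTTTGCATTCCCTGAGACAGTGTGGCCGAGTGAGTCCCTACAAA
AGTACTGCCTCTTTGCCGCATGAGCCAAAAAATCCCGACACACTTAATATAGCCCCGGTC
TCAGCGGCTGGGATAACGGTACCTCTTAGGTCGTCGTACCGGACATCGACCGTTACACGT
CAATTATCGTTGTCTAAATCGTTATGGCGTACCCAACTTACATCAGGTATGCTTTCTGAA
GACGGGATCGGCAAGCTCGCCGAGCACCGCGTGGTGTTGTCAGCCAA
>chr0004
CATGCCGCACCACTGTCGTAAGATCCCACGCGACACGTCACCGCAGACAGTACGGATCCG
GAAAGTTCCATCGCCTCTATTGAGAAGGACACTGCATTCGAGGACAAAAAAGTGTTTAGC
CGGCGACAAACCGACTCGCAAGAGATGATCCCCCCCCCCATGCCGGCGCTCCGTTTCAGA
CTCTCACCGAAACAGTACCGTCGATGCGGCCAAGTACGGGTATTCGTAATGAAGTTACGG
GGAGGCGTTCATTTCACGCAAGAGTGACACAAGGGTAAATAAATGTGCTTGGTCTGCCAA
ATTAATTAGCGTGTGCCGATCCGCAAGGTGCATGACGGCGGGAGTCTGCACTGCATAGAC
ACGGCCCGCCTTACGTCCATTTTATTGTAGGACTCGGACGCAGGATATGAACGCAGAATG
CACAATCGCTCGGTCCTACGTGATGTCCGTACAACATACGAGTGAGCTGTCAGGCCTGAT
TGTCCTAATGCGCGGGGATAGTGTCCGCTATAGGGCCCCTAACCGCGCTGTCTACCATAC
TACACGGCGGGCGGCCGCGAACCGCCTTTACGCTAATCCCCCGTAGCAGTGGTTGTATTT
CCTGCGTCCTGAAGATGGGCGAGACCGTTGGCATCGACCGAAAGTGTACGTAGATGTCTG
AGACAGGATCTTTGAATGAGTTAGCGCGCAACCTACACGGTTTTGTTTGATCAGGGGAGC
ACGGTCTCTAGGACGAGTCCACGAAGTCGGGCCCGATATTTGGCGACGCGGGTTTCCTTC
TTTTGCGAGGTACGCAAAACGGCTACACCGATTTACGCTTCAGAGTATCCCAGCGCCTCA
AGAGTTTGTCTCACGGCGAAATTCTGCCTCATCAAGAAGTGTGTTTTCGTCCGATCTTCT
GACCGCATCCTTCGATCCGTCTTCCTGGCATCCCCTAATTCCATATGGCCCGAGGCATAT
GGCTTCTAACGGGTTTTAGTTTAGGCTCAATCAGAGCGGCATTAGAATGGTGGCCCCCTG
ATTATTGACCGTTACGTGGGGTGATAATGTAAAGTACTTTCGACGGCGGTATTTATAAAA
CGCGAGCGCTGCTTCTCCAGTGACGCTCAGGTACTGTGATCCACAAAGGTCTCGTACCTA
CCTAAGACGGCTAAACTCCATGCGAGCTAGAGATCTTGCGTCACCCTGCAGGACGCTCAT
AAGTCACGTATGGTTCACGTTGACCACGTGACTGAACTATTGTGCATTGGGTTGTTTTTG
CGACACGTGTTCGAATGAGGTGCCATCGATGGTGCACTCAACCGAGCTTTATCTGCCGCA
TCCTTGCTTAAGGACGATGCGATCTAGAGTATACGAAACCGCGAGTTCTATATGACCCAG
TGTCGGACCCAGGAGCCCACCGTGAGATAGTACAAGCAGGGATTCAGCAAAAGCGCTTAA
ATTACCTTAGTCGCTTATTAGACCGAACGCAGGATCACCCGCGTCGCCACACTTTGGTGA
AGGGGTTATCTTAGGAACCGGAACTCTTGGAGAAAATCCGGAGGCAGCCGACCCTGTAGG
TTGTCCCGGACGCGAACCTGCGAGTGTTACGAGTCATGGGATAGTGTTAT
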