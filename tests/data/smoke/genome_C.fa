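>chr0000
TGTCAGCGTCTACTAGCGTTTGCTAACGTCTCTGGAGTTTTATCGCAATTCCAATGAAGT
TAGAAACCGCCTGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTT
GACTGAGAGACCTGGCCTTAACCCCTCTGCCCCCCCCCCATGCGGCCTCGAGATCGGCAC
GTTTTTCATCGTTATAAGCGAAGAGAAACAGGGTGGCATTGGCGGCCGTCAAAAAAAGGG
GAGATAAACCAAGAGACCTTCCTGCATCACGATCGGTTCAGTTGGGAACTCCTGAGAGTC
TGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACAAGTAGGGGGAT
ACTGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCAT
CAGTAGTATCAAAGTTGTTCACGAGCGTGGGCCTGCATCTCGAAGGGGATCGAAGTAAAG
CTCTAGTGAAGAAGGTCACGCAGTGGGGCAACCGCGGGCCCGAGGAACGCGGGCACCTTA
ACGACCGTCAAGGTATTGTACCTGAGGTGTCTTTTCTGGCGCGAATTAAATCCGGCACTG
CAGATGGGCTACGTAATATGAAAAGACCACGGGTACGACGGACCCCTCGATGCGTGTTTC
TGCCAAATTGCTATTTGAAATATCTGACGGATGAAGAACACGAGGCACCTACGAGACAAT
TATTGAGCCGACTCGAGCGAAAATGCACAGGTTCCCTGCTGGGAGAATAGATAAGTTACA
GCGTTTACCGCCTTGCCCAGGACAATGATTAACCAGGTGTCAGGCGAACTTGCTTAGGTC
CGGGCGTCAGCCTTACGCTCTCTTCCATGTCTGATTGTGGTGAGGCGGAATGAGACTTTC
CTTTGTCTCAGAAACCAAAATACTCCGGACCGCTCCCGCACCCATCGCGGCCGCCTAACA
GAATGGAGATAATTAATGGGGTAAACAACCTTCTTGGTATACTTACTACGAGCGTGTATG
TTGGGTAGTTCACTCCATCCAGCTTGAGTTCAAAGGCTAGTCGAGCGCTCAGACTTTCGA
TCATCAGCGTCCATCACTAATAAGATTTGTAGTTGGAAGTGCGCAGTACACCAGTGTTTT
ATAGTGGGCAGAGTAATTGCTACGACGAACTCGCCGTAACCGGTTAAATAGAAATATAAA
CCGGGCCACACCGAGCCTCGAAGATAGCTCTGAACCTGTGAGGTCACACGGGATCTAGGT
TGAAGGCCACCAAAGTGGCATCACTACGCTCTATCCCGCATGTATGTGACCCCGACTCAA
TCCTATACCTGTTAGCTGGCGTACTGGGCACTACAAGATCGGTCCTGCATAATCAACCCC
GCCTG
>chr0001
CCATTCGCGGATGTTGTTCTCGTCTATGAGTTACGTCATTATGACCCTTTTGGAAAGACT
TTACTTATCCATGCACCAAAGGTAAGAATGGAGATCAGCTCTGGGGTGGCTAATTCGGCA
GCCAACTGTCGGGAGCGCGGAAGGATCTTACCCCCCCCCATGGTCACCATGATCACAACG
TCACCCAAATCAGACAGTCGGCCGCGACACGGTATCTGCGTGGTTCCCATAAGAGTGAGT
TTAAGTGCACTTTTGTTCGTAGATCGTGTGCTCATACTCTGTTCTTCATATGGGTTGAGC
GTACTCTGATTAGGGCCCTCTCAGACAGAGCTAGCCCTCATACTCCCATCCCGCGTTCGA
CAGTGCACTTCTCGCTTCGCAGTAACCATCGTTTTAGCCGATAGGGTACTTTGCTATAGG
GGGAGGATAAAACAGCGCGTCAGAATTATCTCTAGCTGTGAGCGAGTACGAGAGTTTTTC
GAAATTCAATACAGTTATTGAGGAAAGCAATTATCAGACCACCATTAAAGTTTGGCCATT
CAAACTGTGCTCAGTGGCGACGCGCGTCGAGCGCACTTTGCGTGAACACCGTGGGTCGAT
GTTGATGTCGCACAGACTCAGCAAAGCATTACAGGTAGACTGTTCGTCTACTGGGAAGCG
GCATGAGAGCTCTTAGCAGCCACGCTCATCAATCCGGTTCTGACCAAGTAAGGGTAGGGA
CTTCGGGGTGAATTCCCTACGCGGTCGTTCAGGGGTTCACATTGGCTGTCATTTAGGCGT
GTCTGTTATGCTTCCACGTATAATATGGTGTGTCCATCTGCGAAGCCGCTGATTACCAGT
TCGTGCGGCATGTGGTATCACCCTTCGCTCAAGGACTTTGATATGCTAGATACGCACGGC
GCGTACAAGCATGGCCAAGACCTGCCCTTTAGCGTTCTGCCACAAATAATACTACGTCAA
TTATGCCTACCGTGTGCCAACTGCTCCTCGATCCTGCAGAGCGCTCCACTACCCATTTTT
ATTGCCTTAAATGCCCTCACATGTGGAATCCAAGAACCTATTCTGCGTAATGCCACTGGC
CATGCTGTACGCGAAAGAAATGCATGGCCAGCTCTCGAAGGTTAAACGAAGTGAACATGG
CAACCAAGTTGAGAAAACGAGTCTGTCGCTAGACGGCCCCATCAAATTACGAACTCGTAC
CTGCCTATGGGTACAAAGGAGCGGGTTTCACTCCAGCCGTGCCATTAGGGAAGAGGTGTG
GGTGTAACTCGCTGTGGGGTGTTACGGCTACCATATTACATGCTAACAGGTGATGAGCCT
GCTCTACTGCGCTGTTTTCCCGCCGTTTTGATTGCGTACGGCTGCATCGGTGGGAGGGCG
GGTCCAGGGAGTACCCACTAATTTATGGTTTCGCCACCATCGAGGGGGTGACCGGATCGG
CACCATGACAGTGAGCGTGCTTTTGAGATTTCTCGTGAGTCGGGTATGCTGCTACATAAC
TTTATCGCTCCGAGGAATTGACTTAGTAGTAGCCAAAAGAGCCCATGGCAACTCAAGCCG
ATCCAGGGCAGGCCTAGACTAACTGCGATTAGGCGTGGACTGCGTATGGTAGGTCTTTCC
TGCTCGAAAAA
>chr0002
TCATGCTTCATTAGGGGATACCCTGAAGCACCTCCGGGGTGTTTCCGGAGAGAGACGTAT
GGTGATAGCCACACGTCCTTGCTGCACTTGGCTTCTAGGTACAACTGGCGTTGCCGGTGG
AAGTAGTTGTACAGACCTGAGTGTCCGTGCCCCCCCCCCATGCGATCGGTACGATTAGTC
GGTATTATGGATGCAGCGGAGCTCCCATTACGTGCCATTCATAAACTACTTGCACCCAAT
TTATTGTCCCGGGCTACGTACATTGGGTTGTGTACGCAGAACTATGGCGTGTGGGGATTC
ATAAGGGCAGCCTGCACGAAGAGTGTACCGGATCTAATACCGGCCGTCCTATGGTGAACC
CGATGGACGGGCGGAAATGGCTAAAGTGCGGGAACGTGAGCGCCGACGGAATGCAAAGAT
AGGACCTATCAGTTTACGATCGGGGTGTCTAGCACCATCCTTCCACGGCCGCCTACGAGA
TCACGGCCCTGCAACGATGTCAAGAAGAACTTTAGCTATCTAGGTCTCAACCGTCGTCAT
ATCCCTTTACTGTCACTGGCACTCAGCCACCAACCCGCCCGGTCTGAAGTTATACGTGAG
GTTAGGTAGTGATCAGACCTCGTCTGGCTGCTTGTCATCTCTAGTGCATGGAATCTTCCG
CGAACTTAACTGGGCATATTTTCCCAGATGCCCTCAAGTTCCCGGTTAGACCCGCAGATG
ACGATGGACCCAGTGCAGTGGACCTCCTTACAGTAACACTATTTCACAGGAACGGTGCCA
GGTGTCGATTTCGGACGAGTGCCCTTCGTACCCTGGCTCAGTTATGGCTTCCGAGTCAGA
GTTACCACGCCTGGAAGCCGTTCGCGGCAGTAGACTTGCTCGGCTACCGCGGCCTATAGC
CGTAATGTTGTGAACATCAGCGCTAATGAATCGGGCGTGCTATGAGAACGATGTTGGGAA
AGGTGTTTTGCGTTGAGAATCTATATCCGGAGGTCGATTTGCCGACCGTGGTCGAGAGTA
AGTGGACTAGCTTAATACACGATCGGCATGGATGCCATAGCGCTTTCACCTCGGGCTAGG
ACTCATATGCGGAAGAAACATATAGATGGGATTTGGGGTTGTCTCCGATTTCCCCGATGG
TTATGGAGTGGTTGCCATGTAGTTATATAAGAATCCACTTAAAATCGTAGTCCACTGTCT
TTGCAGGGTACTGGGCGACCATGCTCCGATTTGGGGACTTCGTAAAAACTGTGCTTATGT
ATAGAAGGTAGAGATTCGGTTGACGGAGCCACCCAAACCACAGGAGGGATCGACTACGCC
ACTACTCTGTTGCAACTACTAAGGTGAGAAGGGCCGCTTCAGACCTTTCAATGTGCACGG
GTCCGCGGTATCCCAACCGGCTACAGTTGAAACCATAATTCGGTCCAAAGGCG
>chr0003
AACAACCGCTCCTACGAGGGTTACGCCGGCCGCCTCTGGAGTTGATCTGCAATGGCTATA
GATGCGTCGATCCGCAGGGGTACTTTACACATAGGGAAGCTATCAGAACAACGACGCAAG
ATTGGACATAACCCACTGTGCATGTTACTTCCCCCCCCCATGGTAAGAGAAACTGAACTC
TTATGCCGTCTAGGGGCCGGGCCAATTCAGGGGACATTAAAATTAGCAAGCAGCTCAGAG
GTTGCGAGAGTCCTTATTTTGTGCCTAACCGGAAATGACCTAACGTCGCCCGGAGTGCGT
CTCTGGCTGAAGAGATGAGCTTTTTGCAAGTGTAATATACCGGCCTGTTAAGCGTTGGCG
GAGGGTTTGTGAGCAATAAACGCCGGTACAGTCCCCTTGAAATTGCTAAGTCGAGTCCTT
TTGCTACGCTACAATGTTTAACCAACGTCTCAAGTGTTAGCGTTTTCTAGTCGTCTTTGA
GGGCAATAGGGCTCTCAACTGGGGTGTGGCAAAAAACACTGCGCGGTTAACGCCCAGCAT
ACGGCCAACTTTATCCCCCGATACGCCCGGGGCTTGTTACTCCTTCGCCGAAAACGTGCT
CACAAGGTTAGCCGTGTTAGTTTCTGGGACAGGTGGGTAATTGTAATCCTTCGCTCCCTG
AACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGACAGAATTAAACGACTTAGG
TTGCGACGCGTGACACTGCCGTCCGGTAAATTCTGGCGTGCATTTAGATGTGAGCTTCTA
TAGTCATCACGGAAGAGCCTTGCTGTGTTGAGGGAGACTCAGAAGTATAGGCGTCGGTCG
GGGCCATTTGCATATCTGCTCCACTGAGCGTAGTAGGCACGGGTGCGACGGTCGGCACCC
ACGCGTATTCCCAGGGAAAACCCAATCTATCCTGCGGCAGAACTAGTAGCCGAGCGTCAA
CAGGATTAACAACCGCGCCGTCTTCTTTTTAGACATACTACGATGACCACCCTTGTTGCG
TGCTCAGCCAATGCTTCCCTCTGTCCACTTAGTCTCACATGTGAATCCAACAGCTCCTAA
TCGCAGAACCAACTCCTTTTGCATTCCCTGAGACAGTGTGGCCGAGTGAGTCCCCACAAA
AGTACTGCCTCTTTGCCGCATGAGCCAAAAAATCCCGACACACTTAATATAGCCCCGGTC
TCAGCGGCTGGGATAACGGTACCTCTTAGGTCGTCGTACCGGACATCGACCGTTACACGT
CAATTATCGTTGTCTAAATCGTTATGGCGTACCCAACTTACATCAGGTATGCTTTCTGAA
GACGGGATCGGCAAGCTCGCCGAGCACCGCGTGGTGTTGTCAGCCAA
>chr0004
CATGCCGCACCACTGTCGTAAGATCCCACGCGACACGTCACCGCAGACAGTACGGATCCG
GAAAGTTCCATCGCCTTTATTGAGAAGGACACTGCATTCGAGGACAAAAAAGTGTTTAGC
CGTCGACAAACCGACTCGCAAGAGATGATCCCCCCCCCCATGCCGGCGCTCCGTTTCAGA
CTCTCACCGAAACAGTACCGTCGATGCGGCCAAGTACGGGTATTCGTAATGAAGTTACGG
GGAGGCGTTCATTTCACGCAAGAGTGACACAAGGGTAAATAAATGTGCTTGGTCTGCCAA
ATTAATTAGCGTGTGCCGATCCGCAAGGTGCATGACGGCGGGAGTCTGCACTGCATAGAC
ACGGCCCGCCTTACGTCCATTTTATTGTAGGACTCGGACGCAGGATATGAACGCAGAATG
CACAATCGCTCGGTCCTACGTGATGTCCGTACAACATACGAGTGAGCTGTCAGGCCTGAT
TGTCCTAATGCGCGGGGATAGTGTCCGCTATAGGGCCCCTAACCGCGCTGTCTACCATAC
TACACGGCGGGCGGCCGCGAACCGCCTTTACGCTAATCCCCCGTAGCAGTGGTTGTATTT
CCTGCGTCCTGAAGATGGGCGAGACCGTTGGCATAGACCGAAAGTGTACGTAGATGTCTG
AGACAGGATATTTGAATGAGTTAGCGCGCAACCTACACGGTTTTGTTTGATCAGGGGAGC
ACGGTCTCTAGGACGAGTCCACGAAGTCGGGCCCGATATTTGGCGACGCGGGTTTCCTTC
TTTTGCGAGGTACGCAAAACGGCTACACCGATTTACGCTTCAGAGTATCCCAGCGCCTCA
AGAGTTTGTCTCACGGCGAAATTCTGCCTCATCAAGAAGTGTGTTTTCGTCCGATCTTCT
GACCGCATCCTTCGATCCGTCTTCCTGGCATCCCCTAATTCCATATGGCCCGAGGCCTAT
GGCTTCTAACGGGTTTTAGTTTAGGCTCAATCAGGGCGGCATTAGAATGGTGGCCCCCTG
ATTATTGACCGTTACGTGGGGTGATAATGTAAAGTACTTTCGACGGCGGTATTTATAAAA
CGCGAGCGCTGCTTCTCCAGTGACGCTCACGTACTGTGATCCACAAAGGTCTCGTACCTA
CCTAAGACGGCTAAACTCCATGCGAGCTAGAGATCTTGCGTCACCCTGCAGGACGCTCAT
AAGTCACGTATGGTTCACGTTGACCACGTGACTGAACTATTGTGCATTGGGTTGTTTTTG
CGACACGTGTTCGAATGAGGTGCCATCGATGGTGCACTCAACCGAGCTTTATCTGCCGCA
TCCTTGCTTAAGGACGCTGCGATCTAGAGTATACGAAACCGCGAGTTCTATATGACCCAG
TGGCGGACCCAGGAGCCCACCGTGAGATAGTACAAGCAGGGATTCAGCAAAAGCGGTTAA
ATTACCTTAGTCGCTTATTAGGCCGAACGCAGGATCACCCGCGTCGCCACACTTTGGTGA
AGGGGTTATCTTAGGAACCGGAACTCTTGGAGAAAATCCGGAGGCAGCCGACCCTGTAGG
TTGTCCCGGACGCGAACCTGCGAGTGTTACGAGTCATGGGATAGTGTTAT
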