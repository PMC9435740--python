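>chr0000
TGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTTTTATCGCAATTCCAATGAAGT
TAGAAACCGCCTGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTT
GACTGAGAGACCTGGCCTTAACCCCTCTGCCCCCCCCCCATGCGGCCTCGAGATCGGCAC
GTTTTTCATCGTTATAAGCGAAGAGAAACAGGGTGGCATTGGCGGCCGTCAAAAAAAGGG
GAGATAAACCAAGAGACCTTCCTGCATCACGATCGGTTCAGTTGGGAACTCCTGAGAGTC
TGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACAAGTAGGGGGAT
ACTGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCAT
CAGTAGTATCAAAGTTGTTCACGAGCGTGGGCCTGCATCTCGAAGGGGATCGAAGTAAAG
CTCTAGTGAAGAAGGTCACGCAGTGGGGCAACCGCGGGCCCGAGGAACGCGGGCACCTTA
ACGACCGTCAAGGTATTGTACCTGAAGTGTCTTTTCTGGCGCGAATTAAATCCGGCACTG
CAGATGGGCTACGTAATATGAAAAGACCACGGGTACGACGGACCCCTCGATGCGTGTTTC
TGCCAAATTGCTATTTGAAATATCTGACGGATGAAGAACACGAGGCACCTACGAGACAAT
TATTGAGCCGACTCGAGCGAAAATGCACAGGTTCCCTGCTGGGAGAATAGATAAGTTACA
GCGTTTACCGCCTTGCCCAGGACAATGATTAACCAGGTGTCAGGCGAACTTGCTTAGGTC
CGGGCGTCAGCCTTACGCTCTCTTCCATGTCTGATTGTGGTGAGGCGGAATAAGACTTTC
CTTTGTCTCAGAAACCAAAATACTCCGGACCGCTCCCGCACCCATCGCGGCCGCCTAACA
GAATGGAGATAATTAATGGGGTAAACAACCTTCTTGGTATACTTACTACGAGCGTGTATG
TTGGGTAGTTCACTCCATCCAGCTTGAGTTCAAAGGCTAGTCGACCGCTCAGACTTTCGA
TCATCAGCGTCCATCACTAATAAGATTTGTAGTTGGAAGTGCGCAGTACACCAGTGTTTT
ATAGTGGGCAGAGTAATTGCTACGACGAACTCGCCGTAACCGGTTAAATAGAAATATAAA
CCGGGCCACACCGAGCCTCGAAGATAGCTCTGAACCTGTGAGGTCACACGGGATCTAGGT
TGAAGGCCACCAAAGTGGCTTCACTACGCTCTATCCCGCATGTATGTGACCCCGACTCAA
TCCTATACCTGTTAGCTGGCGTACTGGGCACTACAAGATCGGTCCTGCATAATCAACCCC
GCCTG
>chr0001
CCATTCGCGGATGTTGTTCTCGTCTATGAGTTACGTCATTATGACCCTTTTGGAAAGACT
TTCCTTATCCATGCACCAAAGGTAAGAATGGAGATCAGCTCTGGGGTGGCTAATTCGGAA
GCCAACTGTCGGGAGCGCGGAAGGATCTTACCCCCCCCCATGGTCACCATGATCACAACG
TCACCCAAATCAGACAGTCGGCCGCGACACGGTATCTGCGTGGTTCCCATAAGAGTGAGT
TTAAGTGCACTTTTGTTCGTAGATCGTGTGCTCATACTCTGTTCTTCATATGGGTTGAGC
GTACTCTGATTAGGGCCCTCTCAGACAGAGTTAGCCCTCATACTCCCATCCCGCGTTCGA
CAGTGCACTTCTCGCTTCGCAGTAACCATCGTTTTAGCCGATAGGGTACTTTGCTATAGG
GGGAGGATAAAACAGCGCGTCAGAATTATCTCTAGCTATGAGCGAGTACGAGAGTTTTTC
GAAATTCAATACAGTTATTGAGGAAAGCAATTATCAGACCACCATTAAAGTTTGGCCATT
CAAACTGTGCTCAGTGGCGACGCGCGTCGAGCGCACTTTGCGTGAACACCGTGGGTCGAT
GTTGATGTCGCACAGACTCAGCAAAGCATTACAGGTAGACTGTTCGTCTACTGGGAAGCG
GCATGAGAGCTCTTAGCAGCCACGCTCATCAATCCGGTTCTGACCAAGTAAGGGTAGGGA
CTTCGGGTTGAATTCCCTACGCGGTCGTTCAGGGGTTCACATTGGGTGTCATTTAGGCGT
GTCTGTTATGCTTCCACGTATAATATGGTGTGTCCATCTGCGAAGCCGCTGATTACCAGT
TCGTGCGGCATGTGGTATCACCCTTCGCTCAAGTACTTTGATATGCTAGATACGCACGGC
GCGTACAAGCATGGCCAAGACCTGCCCTTTAGCGTTCTGCCACAAATAATACTACGTCAA
TTATGCCTACCGTGTGCCAACTGCTCCTCGATCCTGCAGAGCGCTCCACTACCCATTTTT
ATTGCCTTAAATGCCCTCACATGTGGAATCCAAGAACCTATTCTGCGTAATGCCACTGGC
CATGCTGTACGCGAAAGAAATGCATGGCCAGCTCTCGAAGGTTAAACGAAGTGAACATGG
CAACCAAGTTGAGAAAACGAGTCTGTCGCTAGACGGCCCCATCAAATTACGAACTCGTAC
CTGCCTATGGGTACAAAGGAGCGGGTTTCACTCCAGCCGTGCCATTAGGGAAGAGGTGTG
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
AAGTAGTTGTACAGTCCTGAGTGTCCGTGCCCCCCCCCCATGCGATCGGTACGATTAGTC
GGTATTATGGATGCAGCGGAGCTCCCATTACGTGCCATTCATAAACTACTTGCACCCAAT
TTATTGTCCCGGGCTACGTACATTGGGTTGTGTACGCAGAACTATGGCGTGTGGGGATTC
ATAAGGGCAGCCTGCACGAAGAGTGTACCGGATCTAATACCGGCCGTCCTATGGTGAACC
CGATGGACGGGCGGAAATGGCTAAAGTGCGGGAACGTGAGCGCCGACGGAATGCAAAGAT
AGGACCTATCAGTTTACGATCGGGGTGTCTAGCACCATCCTTCCACGGCCGCCTACGAGA
TCACGGCCCTGCAACGATGTCAAGAAGAACTTTAGCTATCTAGGTCTCAACCGTCGTCAT
ATCCCTTTACTGTCACTGGCACTCAGCCACCAACCCGCCCGGTCTGAAGTTATACGTCAG
GTTAGGTAGTGATCAGACCTCGTCTGGCTGCTTGTCATCTCTAGTGCATGGAATCTTCCG
CGAACTTAACTGGGCATATTTTCCCAGATGCCCTCAAGTTCCCGGTTAGACCCGCAGATG
ACGATGGACCCAGTGCAGTGGACCTCCTTACAGTAACACTATTTCACAGGAACGGTGCCA
GGTGTCGATTTCCGACGAGTGCCCTTCGTACCCTGGCTCAGTTATGGCTTCCGAGTCAGA
GTTACCACGCCTGGAAGCCGTTCGCGGCAGTAGACTTGCTCGGCTACCGCGGCCTATAGC
CGTAATGTTGTGAACATCAGCGCTAATGAATCGGGCGTGCTATGAGAACGATGTTGGGAA
AGGTGTTTTGCGTTGAGAATCTATATCCGGAGGTCGATTTGCCGACCGTGGTCGAGAGTA
AGTGGACTAGCTTAATACACGATCGGCATGGATGCCATAGCGCTTTCACCTCGGGCCAGG
ACTCATATGCGGAAGAAACATATAGATGGGATTTGGGGTTGTCTCCGATTTCCCCGATGG
TTATGGAGTGGTTGCCATGTAGTTATATAAGAATCCACTTAAAATCGTAGTCCACTGTCT
TTGCAGGGTACTGGGCGACCATGCTCCGATTTGGGGACTTCGTAAAAACTGTGCTTATGT
ATAGAAGGTAGAGATTCGGTTGACGGAGCCACCCAAACCACAGGAGGGATCGACTACGCC
ACTACTCTGTTGCAACTACTAAGGTGAGAAGGGCCGCTTCAGACCTTTCAATGTGCACGG
GTCCGCGGTATCCCAACCGGCTACAGTTGAAACCCTAATTCGGTCCAAAGGCG
>chr0003
AACAACCGCTCCTACGAGGGTTACGCCGGCCGCCTCTGGAGTTGATCTGCAATGGCTATA
GATGCGTCGATCCGCAGGGGTACTTTACACATAGGGAAGCTATCAGAACAACGACGCAAG
ATTGGACATAACCCACTGTGCATGTTACTTCCCCCCCCCATGGTAAGAGAAACTGAACTC
TTATGCCGTCTAGGGGCCGGTCCAATTCAGGGGACATTAAAATTAGCAAGCAGCTCAGAG
GTTGCGAGAGTCCTTATTTTGTGCCTAACCGGAAATGACCTAACGTCGCCCGGAGTGCGT
CTCTGGATGAAGAGATGAGCTTTTTGCAAGTGTAATATACCGGCCTGTTAAGCGTTGGCG
GAGGGTTTGTGAGCAATAAACGCCGGTACAGTCCCCTTGAAATTGCTAAGTCGAGTCCTT
TTGCCACGCTACAAGGTTTAACCAACGTCTCAAGTGTTAGCGTTTTCTAGTCGTCTTTGA
GGGCAATAGGGCTCTCAACTGGGGTGTGGCAAAAAACACTGCGCGGTTAATGCCCAGCAT
ACGGCCAACTATATCCCCCGATACGCCCGGGGCTTGTTACTCCTTCGCCGAAAACGTGCT
CACAAGGTTAGCCGTGTTAGTTTCTGGGACAGGTGGGTAATTGTAATCCTTCGCTCCCTG
AACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGACAGAATTAAACGATTTAGG
TTGCGACGCGTGACACTGCCGTCCGGTAAATTCTGGCGTGCATTTAGATGTGAGCTTCTA
TAGTCATCCCGGAAGAGCCTTGCTGTGTTGAGGGAGACTCAGAAGTATAGGCGTCGGTCG
GGGCCATTTGCATATCTGCTCCACTGAGCATAGTAGGCACGGGTGCGACGGTCGGCACCC
ACGCGTATTCCCAGGGAAAACCCAATCTATCCTGCGGCAGAACTAGTAGCCGAGCGTCAA
CAGGATTAACAACCGCGCCGTCTTCTTTTTAGACATACTACGATGACCACCCTTGTTGCG
TGCTCAGCCAATGCTTCCCTCTGTCAACTTAGTCTCACATGTGAATCCAACAGCTCCTAA
TCGCAGAACCAACTCCTTTTGCATTCCCTGAGACAGTGTGGCCGAGTGAGTCCCCACAAA
AGTACTGCCTCTTTGCCGCATGAGCCAAAAAATCCCGACACACTTAAGATAGCCCCGGTC
TCAGCGGCTGGGATAACGGTACCTCTTAGGTCGTCGTACCGGACATCGACCGTTACACGT
CAATTATCGTTGTCTAAATCGTTATGGCGTACCCAACTTACATCAGGTATGCTTTCTGAA
GACGGGATCGGCAAGCTCGCCGAGCACCGCGTGGTGTTGTCAGCCAA
>chr0004
CATGCCGCACCACTGTCGTAAGATCCCACGCGACACGTCACCGCAGACAGTACGGATCCG
GAAAGTTCCATCGCCTCTATTGAGAAGGACACTGCATTCGAGGACAAAAAAGTGTTTAGC
CGGCGACAAACCGACTCGCAAGAGATGATCCCCCCCCCCATGCCGGCGCTCCGTTTCAGA
CTCTCACCGAAACAGTACCGTCGATGCGGCCAAGTACGGGTATTCGTAATGAAGTTACGG
GGAGGCGTTCATTTCACGTAAGAGTGACACAAGGGTAAATAAATGTGCTTGGTCTGCCAA
ATTAATTAGCGTGTGCCAATCCGCAAGGTGCATGACGGCGGGAGTCTGCACTGCATAGAC
ACGGCCCGCCTTACGTCCATTTTATTGTAGGACTCGGACGCAGGATATGAACGCAGAATG
CACAATCGCTCGGTCCTACGTGATGTCCGTACAACATACGAGTGAGCTGTCAGGCCTGAT
TGTCCTAATGCGCGGGGATAGTGTCCGCTATAGGGCCCCTAACCGCGCTGTCTACCATAC
TACACGGCGGGCGGCCGCGAACCGCCTTTACGCTAATCCCCCGTAGCAGTGGTTGTATTT
CCTGCGTCCTGAAGATGGGCGAGACCGTTGGCATCGACCGAAAGTGTACGTAGATGTCTG
AGACAGGATATTTGAATGAGTTAGCGCGCAACCTACACGGTTTTGTTTGATCAGGGGAGC
ACGGTCTCTAGGACGAGTCCACGAAGTCGGTCCCGATATTTGGCGACGCGGGTTTCCTTC
TTTTGCGAGGTACGCAAAACGGCTACACCGATTTACGCTTCAGAGTATCCCAGCGCCTCA
AGAGTTTGTCTCACGGCGAAATTCTGCCTCATCAAGAAGTGTGTTTTCGTCCGATCTTCT
GACCGCATCCTTCGATCCGTCTTCCTGGCATCCCCTAATTCCATATGGCCCGAGGCCTAT
GGCTTCTAACGGGTTTTAGTTTAGGCTCAATCAGGGCGGCATTAGAATGGTGGCCCCCTG
ATTATTGACCGTTACGTGGGGTGATAATGTAAAGTACTTTCGACGGCGGTATTTATAAAA
CGCGAGCGCTGCTTCTCCAGTGACGCTCAGGTACTGTGATCCACAAAGGTCTCGTACCTA
CCTAAGACGGCTAAACTCCATGCGAGCTAGAGATCTTGCGTCACCCTGCAGGACGCTCAT
AAGTCACGTATGGTTCACGTTGACCACGTGACAGAACTATTGTGCATTGGGTTGTTTTTG
CGACACGTGTTCGAATGAGGTGCCATCGATGGTGCACTCAACCGAGCTTTATCTGCCGCA
TCCTTGCTTAAGGACGATGCGATCTAGAGTATACGAAACCGCGAGTTCTATATGACCCAG
TGTCGGACCCAGGAGCCCACCGTGAGATAGTACAAGCAGGGATTCAGCAAAAGCGGTTAA
ATTACCTTAGTCGCTTATTAGGCCGAACGCAGGATCACCCGCGTCGCCACACTTTGGTGA
AGGGGTTATCTTAGGAACCGGAACTCTTGGAGAAAATCCGGAGGCAGCCGACCCTGTAGG
TTGTCCCGGACGCGAACCTGCGAGTGTTACGAGTCATGGGATAGTGTTAT
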