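>chr0000
TGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTTTTATCGCAATTCCAATGAAGT
TAGAAACCGCCTGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTT
GACTGAGAGACCTGGCCTTAACCCCTCTGCCCCCCCCCCATGAGGCCTCGAGATCGGCAC
GTTTTTCATCGTTATAAGCGAAGAGAAACAGGGTGGCATTGGAGGCCGTCAAAAAAAGGG
GAGATAAACCAAGAGACCTTCGTGCATCACGATCGGTTCAGTTGGGAACTCCTGAGAGTC
TGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACAAGTAGGGGGAT
ACTGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCAT
CAGTAGTATCAAAGTTGTTCACGAGCGTGGGCCTGCATCTCGAAGGGGATCGAAGTAAAG
CTCTAGTGAAGAAGGTCACGCAGTGGGGCAACCGCGGGCCCGAGGAACGCGGGCACCTTA
ACGACCGTCAAGGTATTGTACCTGAGGTGTCTTTTCTGGCGCGAATTAAATCCGGCACTG
CAGATGGGCTACGTAATATGAAAAGACCACGGGTACGACGGACCCCTCGATGCGTGTTTC
TGCCAAATTGCTATTTGAAATATCTGACGGATGAAGAACACGAGGCACCTACGAGACAAT
TATTGAGCCGACTCGAGCGAAAATGCACAGGTTCCCTGCTGGGAGAATAGATAAGTTACA
GCGTTTACCGCCTTGCCCAGGACAATGATTAACCAGGTGTCAGGCGAACTTGCTTAGGTA
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
TTACTTATCCATGCACCAAAGGTAAGAATGGAGATCAGCTCTGGGGTGGCTAATTCGGAA
GCCAACTGTCGGGAGCGCGGAAGGATCTTACCCCCCCCCATGGTCACCATGATCACAACG
TCACCCAAATCAGACAGTCGGCCGCGACACGGTATCTGCGTGGTTCCCATAAGAGTGAGT
TTAAGTGCACTTTTGTTCGTAGATCGTGTGCTCATACTCTGTTCTTCATATGGGTTGAGC
GTACTCTGATTAGGGCCCTCTCAGACAGAGTTAGCCCTCATACTCCCATCCCGCGTTCGA
CAGTGCACTTCTCGCTTCGCAGTAACCATCGTTTTAGCCGATAGGGTACTTTGCTATAGG
GGGAGGATAAAACTGCGCGTCAGAATTATCTCTAGCTGTGAGCGAGTACGAGAGTTTTTC
GAAATTCTATACAGTTATTGAGGAAAGCAATTATCAGACCACCAATAAAGTTTGGCCATT
CAAACTGTGCTCAGTGGCGACGCGCGTCGAGCGCACTTTGCGTGAACACCGTGGGTCGAT
GTTGATGTCGGTCAGACTCAGCAAAGCATTACAGGTAGACTGTTCGTCTACTGGGAAGCG
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
GGTGTAACTCGGTGTGGGGTGTTACGGCTACCATATTACATGCTAACAGGTGATGAGCCT
GCTCTACTGCGCTGTTTTCCCGCCGTTTTGATTGCGTACGGCTGCATCGGTGGGAGGGCG
GGGCCAGGGAGTACCCACTAATTTATGGTTTCGCCACCATCGAGGGGGTGACCGGATCGG
CACCATGACAGTGAGCGTGCTTTTGAGATTTCTCGTGAGTCGGGTATGCTGCTACATAAC
TTTATCGCTCCGAGGAATTGACTTAGTAGTAGCCCAAAGAGCCCATGGCAACTCAAGCCG
ATCCAGGGCAGGCCTAGACTAACTGCGATTAGGCGTGGACTGCGTATGGTAGGTCTTTCC
TGCTCGAAAAA
>chr0002
TCATGCTTCATTACGGGATACCCTGAAGCACCTCCGGGGTGTTTCCGGAGAGAGACGTAT
GGTGATAGCCACACGTCCTTGCTGCACTTGGCTTCTAGGTACAACTGGCGTTCCCGGTGG
AAGTAGTTGTACAGACCTGAGTGTCCGTGCCCCCCCCCCATGCGATCGGTACGATTAGTC
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
GGTGTCGATTTAGGACGAGTGCCCTTCGTACCCTGGCTCAGTTATGGCTTCCGAGTCAGA
GTTACCACGCCTGGAAGCCGTTCGCGGCAGTAGACTTGCTCGGCTACCGCGGCCTATAGC
CGTAATGGTGTGAACATCAGCGCTAATGAATCGGGCGTGCTATGAGAACGATGTTGGGAA
AGGTGTTTTGCGTTGAGAATCTATATCCGGAGGTCGATTTGCCGACCGTGGTCGAGAGTA
AGTGGACTAGCTTAATACACGATCGGCATGGATGCCATAGCGCTTTCACCTCGGGCTAGG
ACTCATATGCGGAAGAAACATATAGATGGGATTTGGGGTTGTCTCCGATTTCCCCGATGG
TTATGGAGTGGTTGCCATGTAGTTATATAAGAATCCACTTAAAATCGTAGTCCACTGTCT
TTGCAGGGTACTGGGCGACCATGCTCCGATTTGGGGACTTCGTAAAAACTGTGCTTATGT
ATAGAAGGTAGAGATTCGGTTGACGGAGCCACCCAAACCACAGCAGGGATCGACTACGCC
ACTACTCTGTTGCAACTACTAAGGTGAGAAGGGCCGCTTCAGACCTTTCAATGTGCACGG
GTCCGCTGTATCCCAACCGGCTACAGTTGAAACCCTAATTCGGTCCAAAGGCG
>chr0003
AACAACCGCTCCTAGGAGGGTTACGCCGGCCGCCTCTGGAGTTGATCTGCAATGGCTATA
GATGCGTCGATCCGCAGGGGTACTTTACACATAGGGAAGCTATCAGAACAACGACGCAAG
ATTGGACATAACCCATTGTGCATGTTACTTCCCCCCCCCATGGTAAGAGAAACTGAACTC
TTATGCCGTCTAGGGGCCGGTCCAATTCAGGGGACATTAAAATTAGCAAGCAGCTCAGAG
GTTGCGAGAGTCCTTATTTTGTGCCTAACCGGAAATGACCTAACGTCGCCCGGAGTGCGT
CTCTGGCTGAAGAGATGAGCTTTTTGCAAGTGTAATATACCGGCCTGTTAAGCGTTGGCG
GAGGGTTTGTGAGCAATAAACGCCGGTACAGTCCCCTTGAAATTGCTAAGTCGAATCCTT
TTGCCACGCTACAAGGTTTAACCAACGTCTCAAGTGTTAGCGTTTTCTAGTCGTCTTTGA
GGGCAATAGGGCTCTCAACTGGGGTGTGGCAAAAAACACTGCGCGGTTAATGCCCAGCAT
ACGGCCAACTTTATCCCCCGATACGCCCGGGGCTTGTTACTCCTTCGCCGAAAACGTGCT
CACAAGGTTAGCCGTGTTAGTTTCTGGGACAGGTGGGTAATTGTAATCCTTCGCTCCCTG
AACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGACAGAATTAAACGACTTAGG
TTGCGACGCGTGACACTGCCGTCCGGTAAATTCTGGCGTGCATTTAGATGTGAGCTTCTA
TAGTCATCCCGGAAGAGCCTTGCTGTGTTGAGGGAGACTCAGAAGTATAGGCGTCGGTCG
GGGCCATTTGCATATCTGCTCCACTGAGCGTAGTAGGCACGGGTGCGACGGTCGGCACCC
ACGCGTATTCCCAGGGAAAACCCAATCTATCCTGCGGCAGAACTAGTAGCCGAGCGTCAA
CAGGATTAACAACCGCGCCGTCTTCTTTTTAGACATACTACGATGACCACCCTTGTTGCG
TGCTCAGCCAATGCTTCCCTCTGTCAACTTAGTCTCACATGTGAATCCAACAGCTCCTAA
TCGCAGAACCAACTCCTTTTGCATTCCCTGAGACAGTGTGGCCGAGTGAGTCCCCACAAA
AGTACTGCCTCTCTGGCGCATGAGCCAAAAAATCCCGACACACTTAATATAGCCCCGGTC
TCAGCGGCTGGGATAACGGTACCTCTTAGGTCGTCGTACCGGACATCGACCGTTACACGT
CAATTATCGTTGTCTAAATCGTTATGGCGTACCCAACTTACATCAGGTATGCTTTCTGAA
GACGGGATCGGCAAGCTCGCCGAGCACCGCGTGGTGTTGTCAGCCAG
>chr0004
CATGCCGCACCACTGTCGTAAGATCCCACGCGACACGTCACCGCAGACAGTACGGATCCG
GAAAGTTCCATCGCCTCTATTGAGAAGGACACTGCATTCGAGGACAAAAAAGTGTTTAGC
CGGCGACAAACCGACTCGCAAGACATGATCCCCCCCCCCATGCCGGCGCTCCGTTTCAGA
CTCTCACCGAAACAGTACCGTCGATGCGGCCAAGTACGGGTATTCGTAATGAAGTTACGG
GGAGGAGTTCATTTCGCGCAAGAGTGACACAAGGGTAAATAAATGTGCTTGGTCTGCCAA
ATTAATTAGCGTGTGCCGATCCGCAAGGTGCATGACGGCGGGAGTCTGCACTGCATAGAC
ACGGCCCGCCTTACGTCCATTTTATTGTAGGACTCGGACGCAGGATATGAACGCAGAATG
CACAATCGCTCGGTCCTACGTGATGTCCGTACAACATACGAGTGAGCTGTCAGGCCTGAT
TGTCCTAATGCGCGGGGATAGTGTCCGCTATAGGGCCCCTAACCGCGCTGTCTACCATAC
TACACGGCGGGCGGCCGCGAACCGCCTTTACGCTAATCCCCCGTAGCAGTGGTTGTATTT
CCTGCGTCCTGAAGATGGGCGAGACCGTTGGCATCGACCGAAAGTGTACGTAGATGTCTG
AGACAGGATATTTGAATGAGTTAGCGCGCAACCTACACGGTTTTGTTTGATCAGGGGAGC
ACGGTCTCTAGGACGAGTCCACGAAGTCGGGCCCGATATTTGGCGACGCGGGTTTCCTTC
TTTTGCGAGGTACGCAAAACGGCTACACCGATTTACGCTTCAGAGTATCCCAGCGCCTCA
AGAGTTTGTCTCACGGCGAAATTCTGCCTCATCAAGAAGTGTGTTTTCGTCCGATCTTCT
GACCGCATCCTTCGATCCGTCTTCCTGGCATCCCCTAATTCCATATGGCCCGAGGCCTAT
GTCTTCTAACGGGTTTTAGTTTAGGCTCAATCAGGGCGGCATTAGAATGGTGGCCCCCTG
ATTATTGACCGTTACGTGGGGTGATAATGTAAAGTACTTTCGACGGCGGTATTTATAAAA
CGCGAGCGCTGCTTCTCCAGTGACGCTCAGGTACTGTGATCCACAAAGGTCTCGTACCTA
CCTAAGACAGCTAAACTCCGTGCGAGCTAGAGATCTTGCGTCACCCTGCAGGACGCTCAT
AAGTCACGTATGGTGCACGTTGACCACGTGACTGAACTATTGTGCATTGGGTTGTTTTTG
CGACACGTGTTCGAATGAGGTGCCATCGATGGTCCACTCAACCGAGCTTTATCTGCCGCA
TCCTTGCTTAAGGACGATGCGATCTAGAGTATACGAAACCGCGAGTTCTATATGACCCAG
TGTCGGACCCAGGAGCCCACCGTGAGATAGTACAAGCAGGGATTCAGCAAAAGCGGTTAA
ATTACCTTAGTCGCTTATTAGGCCGAACGCAGGATCACCCGCGTCGCCACACTTTGGTGA
AGGGGTTATCTTAGGAACCGGAACTCTTGGAGAAAATCCGGAGGCAGCCGACCCTGTAGG
TTGTCCCGGACGCGAACCTGCGAGTGTTACGAGTCATGGGATAGTGTTAT
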