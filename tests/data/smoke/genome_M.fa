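>chr0000
TGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTTTTAGCGCAATTCCAATGAAGT
TAGAAACCGCCTGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTT
GACTGAGAGACCTGGCCTTAACCCCTCTGCCCCCCCCCCATGCGGCCTCGAGATCGGCAC
GTTTTTCATCGTTATAAGCGAAGAGAAACAGGGTGGCATTGGCGGCCGTCAAAAAAAGGG
GAGATAAACCAAGAGACCTTCCTGAATCACGATCGGTTCAGTTGGGAACTCCTGAGAGTC
TGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCTTCCGACAAGTAGGGGGAT
ACTGCACGTTAGGACCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCAT
CAGTAGTATCAAAGTTGTTCACGAGCGTGGGCCTGCATCTCGAAGGGGATCGAAGTAAAG
CTCTAGTGAAGAAGGTCACGCAGTGGGGCAACCGCAGGCCCGAGGAACGCGGGCACCTTA
ACGACCGTCAAGGTATTGTACCTGAGGTGTCTTTTCTGGCGCGAATTAAATCCGGCACTG
CAGATGGGCTACGTAATATGAAAAGACCACGGGTACGACGGACCCCTCGATGCGTGTTTC
TGCCAAATTGCTATTTGAAATATCTGACGGATGAAGAACACGAGGCACCTACGAGACAAT
TATTGAGCCGACTCGAGCGAAAATGCACAGGTTCCCTGCTGGGAGAATAGATAAGTTACA
GCGTTTACCGCCTTGCCCAGGACAATGATTAACCAGGTGTCAGGCGAACTTGCTTAGGTC
CGGGCTTCAGCCTTACGCTCTCTTCCATGTCTGATTGTGGTGAGGCGGAATAAGACTTTC
CTTTGTCTCAGAAACCAAAATACTCAGGACCGCTCCCGCACCCATCGCGGCCGCCTAACA
GAATGGAGATAATTAATGGGGTAAACAACCTTCTTGGTATACTTACTACGAGCGTGTATG
TTGGGTAGTTCACTCCATCCAGCTTGAGTTCAAAGGCTAGTCGACCGCTCAGACTTTCGA
TCATCAGCGTCCATCACTAATAAGATTTGTAGTTGGAAGTGCGCAGTACACCAGTGTTTT
ATAGTGGGCAGAGTAATTGCTACGACGAACTCGCCGTAACCGGTTAAATAGAAATATAAA
CGGGGCCACACCGAGCCTCGAAGATAGCTCTGAACCTGTGAGGTCACACGGGATCTAGGT
TGAAGGTCACCAAAGTGGCTTCACTACGCTCTATCCCGCATGTATGTGACCCCGACTCAA
TCCTATACCTGTTAGCTGGCGTACTGGGCACTACAAGATCGGTCCTGCATAATCAACCCC
GCCTG
>chr0001
CCATTCGCGGATGTTGTTCTCGTCTATGTGTTACGTCATTATGACCCTTTTGGAAAGACT
TTACTTATCCATGCACCAAAGGTAAGAATGGAGATCAGCTCTGGGGTGGCTAATTCGGAA
GCCAACTGTCGGGAGCGCGGAAGGATCTTACCCCCCCCCATGGTCACCATGATCACAACG
TCACCCAAATCAGACAGTCGGCCGCGACACGGTATCTGCGTGGTTCCCATAAGAGTGAGT
TTAAGTGCACTTTTGTTCGTAGATCGTGTGCTCATACTCTGTTCTTCATATGGGTTGAGC
GTACTCTGATTAGGGCCCTCTCAGACAGAGTTAGCCCTCATACTCCCATCCCGCGTTCGA
CAGTGCACTTCTCGCTTCGCAGTAACCATCGTTTTAGCCGATAGGGTACTTTGCTATAGG
GGGAGGATAAAACAGCGCGTCAGAATTATCTCTAGCTGTGAGCGAGTACGAGAGTTTTTC
GAAATTCAATACAGTTATTGAGGAAAGCAATTATCAGACCACCATTAAAGTTTGGCCATT
CAAACTGTGCTCAGTGGCGACGCGCGTCGAGCGCACTTTGCGTGAACACCGTGGGTCGAT
GTTGATGTCGCACAGACTCAGCAAAGCATTACAGGTAGCCTGTTCGTCTACTGGGAAGCG
GCATAAGAGCTCTTAGCAGCCACGCTCATCAATCCGGTTCTGACCAAGTAAGGGTAGGGA
CTTCGGGGTGAATTCCCTACGCGGTCGTTCAGGGGTTCACATTGGCTGTCATTTAGGCGT
GTCTGTTATGCTTCCACGTATAATATGGTGTGTCCATCTGCGAAGCCGCTGATTACCAGT
TCGTGCGGCATGTGGTATCACCCTTCGCTCAAGGACTTTGATATGTTAGATACGCACGGC
GCGTACAAGCATGGCCAAGACCTGCCCTTTAGCGTTCTGCCACAAATAATACTACGTCAA
TTATGCCTACCGTGTGCCAACTGCTCCTCGATCCTGCAGAGCGCTCCACTACCCATTTTT
ATTGCCTTAAATGCCCTCACATGTGGAATCCAAGAACCTATTCTGCGTAATGCCACTGGC
CATGCTGTACGCGAAAGAAATGCATGGCCAGCTCTCGAAGGTTAAACGAAGTGAACATGG
CAACCAAGTTGAGAAAACGAGTCTGTCGCTAGACGGCCCCATCAAATTACGAACTCGTAC
CTGCCTATGGGTACAAAGGAGCGGGTTTCACTCCAGCCGTGCCATTAGGGAAGAGGTGTG
GGTGTAACTCGGTGTGGGGTGTTACGGCTACCATATTACATGCTAACAGGTGATGAGCCT
GCTCTACTGCGCTGTTTTCCGGCCGTTTTGATTGCGTACGGCTGCATCGGTGGGAGGGCG
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
TTATTGTCCCGGGCTACGTACATTGGGTTGTGTACGCAGAACTATGGCGTGTGGGGATTC
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
CGTAATGTTGTGAACATCAGCGCTAATGAATCGGGCGTGCTATGAGAACGATGTTGGGAA
AGGTGTTTTGCGTTGAGAATCTATATCCGGAGGTCGATTTGCCGACCGTGGTCGAGAGTA
AGTGGACTAGCTTAATACACGATCGGCATGGATGCCATAGCGCTTTCACCTCGGGCTAGG
ACTCATATGCGGAAGAAACATATAGATGGGATTTGGGGTTGTCTCCGATTTCCCCGATGG
TTATGGAGTGGTTGCCATGTAGATATATAAGAATCCACTTAAAATCGTAGTCCACTGTCT
TTGCAGGGTACTGGGCGACCATGCTCCGATTTGGGGACTTCGTAAAAACTGTGCTTATGT
ATAGAAGGTAGAGATTCGGTTGACGGAGCCACCCAAACCACAGGAGGGATCGACTACGCC
ACCACTCTGTTGCAACTACTAAGGTGAGAAGGGCCGCTTCAGACCTTTCAATGTGCACGG
GTCCGCGGTATCCCAACCGGCTACAGTTGAAACCCTAATTCGGTCCAAAGGCG
>chr0003
AACAACCGCTCCTACGAGGGTTACGCCGGCCGCCTCTGGAGTTGATCTGCAATGGCTATA
GATGCGTCGATCCGCAGGGGTACTTTACACATAGGGAAGCTATCAGAACAACGACGCAAG
ATTGGACATAACCCACTGTGCATGTTACTTCCCCCCCCCATGGTAAGAGAAACTGAACTC
TTATGCCGTCTAGGGGCCGGTCCAATTCAGGGGACATTAAAATTAGCAAGCAGCTCAGAG
GTTGCGAGAGTCCTTATTTTGTGCCTAACCGGAAATGACCTAACGTCGCCCGGAGTGCGT
CGCTGGCTGAAGAGATGAGCTTTTTGCAAGTGTAATATACCGGACTGTTAAGCGTTGGCG
GAGGGTTTGTGAGCAATAAACGCCGGTACGGTCCCCTTGAAATTGCTAAGTCGAGTCCTT
TTGCCACGCTAAAAGGTTTAACCAACGTCTCAAGTGTTAGCGTTTTCTAGTCGTCTTTGA
GGGCAATAGGGCTCTCAACTGGGGTGTGGCAAAAAACACTGCGCGGTTAATGCCCAGCAT
ACGGCCAACTTTATCCCCCGATACGCCCGGGGCTTGTTACTCCTTCGCCGAAAACGTGCT
CACAAGGTTAGCCGTGTTAGTTTCTGGGACAGGTGGGTAATTGTAATCCTTCGCTCCCTG
AACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGACAGAATTAAACGACTTAGG
TTGCGACGCGTGACACTGCCGTCCGGTAAATTCTGGCGTGCATTTAGATGTGAGCTTCTA
TAGTCATCCCGGAAGAGCCTTGCTGTGTTGAGGGAGACTCAGAAGTATAGGCGTCGGTCG
GGGCCATTTGCATATCTGCTCCACTGAGCGTAGTAGGCACGGGTGCGACGGTCGGCACCC
ACGCGTATTCCCAGGGAAAACCCAATCTATCCTGCGGCAGAGCTAGTAGCCGAGCGTCAA
CAGGATTAACAACCGCGCCGTCTTCTTTTTAGACATACTACGATGACCACCCTTGTTGCG
TGCTCAGCCAATGCTTCCCTCTGTCAACTTAGTCTCACATGTGAATCCAACAGCTCCTAA
TCGCAGAACCAACTCCTTTTGCATTCCCTGAGACAGTGTGGCCGAGTGAGTCCCCACAAA
AGTACTGCCTCTTTGCCGCATGAGCCAAAAAATCCCGACACACTTAATATAGCCCCGGTC
TCAGCGGATGGGATAACGGTACCTCTTAGGTCGTCGTACCGGACATCGACCGTTACACGT
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
TGTCCTAATGCGCGGGGATAGTGTCCGCTATAGGGCCCCTAACCGCGCTGTCCACCATAC
TACACGGCGGGCGGCCGCGAACCGCCTTTACGCTAATCCCCCGTAGCAGTGGTTGTATTT
CCTGCGTCCTGAAGATGGGCGAGACCTTTGGCATCGACCGAAAGTGTACGTAGATGTCTG
AGACAGGATATTTGAATGAGTTAGCGCGCAACCTACACGGTTTTGTTTGATCAGGGGAGC
ACGGTCTCTAGGACGAGTCCACGAAGTCGGGCCCGATATTTGGCGACGCGGGTTTCCTTC
TTTTGCGAGGTACGCAAAACGGCTACACCGATTTACGCTTCAGAGTATCCCAGCGCCTCA
AGAGTTTGTCTCACGGCGAAATTCTGCCTCATCAAGAAGTGTGTTATCGTCCGATCTTCT
GACCGCATCCTTCCATCCGTCTTCATGGCATCCCCTAATTCCATATGGCCCGAGGCCTAT
GGCTTCTAACGGGTTTTAGTTTAGGCTCAATCAGGGCGGCATTAGAATGGTGGCCCCCTG
ATTCTTGACCGTGACGTGGGGTGATAATGTAAAGTACTTTCGACGGCGGTATTTATAAAA
CGCGAGCGCTGCTTCTCCAGTGACGCTCAGGTACTGTGATCCACGAAGGTCTCGTACCTA
CCTAAGACGGCTAAACTCCATGCGAGCTAGAGATCTTGCGTCACCCTGCAGGACGCTCAT
AAGTCACGTATGGTTCACGTTGACCACGTGACTGAACTATTGTGCATTGGGTTGTTTTTG
CGACACGTGTTCGAATGAGGTGCCATCGATGGTGCACTCAACCGAGCTTTATCTGCCGCA
TCCTTGCTTAAGGACGATGCGATCTAGAGTATACGAAACCGCGAGTTCTATATGACCCAG
TGTCGGACCCAGGAGCCCACCGTGAGATTGTACAAGCAGGGATTCAGCAAAAGCGGTTAA
ATTACCTTAGTCGCTTATTAGGCCGAACGCAGGATCACCCGCGTCGCCACACTTTGGTGA
AGGGGTTATCTTAGGAACCGGAACTCTTGGAGAAAATCCGGAGGCAGCCGACCCTGTAGG
TTGTCCCGGACGCGCACCTGCGAGTGTTACGAGTCATGGGATAGTGTTAT
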