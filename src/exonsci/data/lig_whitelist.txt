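CCGGCACTGG
TCCGCGTGCG
TCGTGGACTT
ATTCCCGGAA
ACAGCTACCC
GCACCCCGGT
TCGTAGCGCG
CCATACTTAT
ACCGTTTCGG
AGAAAGATCA
GCTATTGTCA
CTATTATGCA
ATCATATTCG
CCTGATCACG
CAGGAGAACT
GCGTCGAATA
TTATGCACCT
GTTTGGTGAC
CTCGATAAGT
GGAAGGGCAT
TTTAGTTGTA
TCCTCGTTCT
TTAGTCTTCG
GTGCAACCAC
ACATAGAGAG
ATGACGCTTC
CCTTCATCGC
GTCGCATGCA
ACCGATGTAC
CCGACAAGTC
AAGCGCCACA
CAAAGAAAAT
GACTCGATTC
CGTCTGGTCC
ATGTCGAATT
ATTGAATAAA
TGGACGGAGT
GGTGAAACTA
TACTCCTCTG
CAGGTCCAAA
ATCTTAATGC
ACCATATCTA
TTCGACCTCG
AGTTCAGAAG
GGACACGGCG
TCCCTGTGAA
AATTTGAGGG
GGTTTTGGCT
GACCAAGCGA
TATGGACCTT
GCACTCCTTG
TCTAATTGCG
CGGACTTCTA
CACCATTAAG
GTGCGTTCAT
GGAGAACTGG
TCCCGAGGGA
CGCAACAGTA
TCATAGGTCA
ATAATCTCTG
TCTTGCCATT
GACTATGAAT
GATGCCAAGC
TGCACGCACG
AAAGTGCGCG
CTACAGATTC
TTACCGTAGT
AACCGACAGC
ACGGTTGGTT
CATGATGTCT
TATGTGCAGT
GCGTCCCACA
CCAAGTATTA
ATACGTAGCA
GACGGTAGAT
GTTTTGGTTA
CGTGGACTAT
ATCGAGAGGC
AATGGGCATG
ACGCCTATTG
AGAGGAATCT
GCCTAGGACT
GTCAGAATCA
AGCGTCAGAA
TCTAGGCCGT
TGCTATCGTG
CAATCGTCAA
CCTCATGATG
ATCCGCACGG
ATGCGGGTAC
CAGATAGTGA
CTTCCGCCCA
GGCTGACCGG
TGTGCTTTAT
TTCTCACAAA
CGCCGTCTCT
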