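ACGTCGGCCA
GGAGACTTAG
GGGTCATGCG
TGGCACCGGG
TATAGAGCTC
CTGCGAAAGT
ACTGAGAACT
CACTCAATAG
GTATTCGGGC
ACCCTCTAAG
GGCCTAAGAA
GACAGTTTTG
TAACCAAAGT
ATCTCAGGTC
ACCTCCGGGT
GGAGGCCGCC
TAGGTTAGGC
CTTGTCCATG
GCACTCGTTT
CCAACTATCT
CTCCCATGGA
CTTAGCGGTT
CTAGAATCAG
CCTGCTGGAC
CGAGTGAGGA
ACGCCTGTTG
AGTTGCAGTC
TGAGACATTA
GTCACACAAC
CTACTGATTT
AGGCGCAGTT
CAAGCGACGA
GCGCAAAGAG
GGATACGTGT
AGCACTTGTC
AAACCTGGGT
ACCATACAAC
GATACCGGTT
TAGCCTCGGG
GATCCAATAA
GTCGAAACTT
CATAAGTATC
GTCCGACGTA
TTAACCCCCT
CTATTTTATA
CTCTCGTGAG
GGTTCCTTAA
ACGGGTTTCG
CTGTGATCCG
GCCCCCCAAT
TTCACTGTTC
AAGGGCCTTG
CTACGGATCC
AGGGTAGGTT
GTATGAGCTC
GTGTTGGCTT
TAGGATGGCG
TCTGATGTGG
GCAATGTGCT
TAAGGTAACT
GTAATAAAGC
CGCAGCCTGT
GCAGCGTTTA
CACGCACAAC
TCTCTTGCCC
AGAATGCTTT
TATACTTGAA
CCCTCTAACC
CTGTATCCGC
CACGACGAAT
ATAAGGGCGA
GTGCAATAGG
TTTTCGGAGT
CAGCCGAAAA
TCCTTGAATG
GAAATGCTCA
ACTACTAGGA
CCTGCCGGGG
ATCTGTCGAC
CACATGCCTC
TTAATTGTTA
CTGGGCCGAG
CGGTAGAGCG
CAACATATCA
TGAATAAGCA
AGCACCGCGC
GTGATGTCGC
CCTTGCCTCG
TTTCGACGCG
GTGGTTGAAA
TGTCCTGGGC
ACAGTGCTAC
CAATTGCGTG
TCTTAACCTG
GGCCAAGGGC
AACCTGAGGC
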