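gene,species,accession,forward,reverse,expected_size
Atoh7,chicken,NC_052537.1,CCAGTCATTTGGATTCAGGACT,AGTGTCTGTTGCCACTTTTTGTCC,378
Hes1,chicken,NC_052540.1,TGTACGGTGGTTTCCAGCTG,AACACGAAACACTGTCGGAG,312
Pax6,chicken,NC_052536.1,CTGGACTGTCAGTTCCAGTTC,CCGATATAATGCCTTCAGTG,245
Ebf3,chicken,NC_052537.1,ACGCATCAAACTGGAAGAAG,GTGTTGCGATGGGTAAGACT,549
Eya2,chicken,NC_052551.1,CAGTGGAAGCCTCTAAGGAC,TTTGCAGAAGGTCCGACGTG,276
Atoh7,mouse,NC_000076.7,AAGCTGTCCAAGTACGAGACACTGC,GTTTCTCCACCTCCTGAATGACGCT,567
Hes1,mouse,NC_000082.7,CACCCTGCAAGTTGGGCAGG,TCTCTCCTAAAATCCAAGTTC,331
Pax6,mouse,NC_000068.8,TGTAGGTCTGCATCCCACAAT,AAGGCCTTTAACTCCCACCG,464
Ebf3,mouse,NC_000073.7,GGTCAGATCCCACAGCACTG,GAGGACACTTGCTAATGTGC,460
Eya2,mouse,NC_000068.8,TTTCTGGAGGATATCCTGTC,ACGCACACTGTCCACATGAC,481
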