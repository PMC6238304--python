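>CYP2D6_INT2_synthetic synthetic 1101-bp stand-in for the functional-gene intron-2 amplicon (generated, not a GenBank record)
TTCATACTAACATAGCCCTCATGGCGTAAATTGGATATAAATAGAAATTTTGTTCACTTGTTATGCGCGA
TTTCCCGAAGGAGAACAGGAGGAACCACGTAAAACACGGAGTTAGGGTCGTAGGAAATTAGGTACGCATT
CGATTGCTTCGGGCGGTTGGCAGTGGGTGGAAGCAAACCCTAGCCCCGCATAACGCGTGGGATCTGTCCT
GTAAAATGACATGAAGGGGGTGACGGATCTACCTGCCAGCATATGACAAGTCTGAAGGTGCCGCCAGTCT
GCCTACAGGAATCAAAACGTGTACACAGCACGTTAAATTATAGGACATAACGGACTTCGTACGGGCAGGG
ATATATGGCTACAGTTCACCAAGAACGCACTAATGCTGATTTAAGACCTTGCATACTGTGGCCACAAGGT
GGGTTGGACGAGGCTAGTGCTTAATTCCGGGTTACATGGGAGTATCTTGATAATTGCAATAGTAATAAAA
TCAACTAAGTAGCTCATTCGAGGTGCACTACTGAAGGGGACTCAGCAGCATGGTACCGTGGACGTCAAAG
GCATTCGACATGATGAAGATTGCCATGTATTACCACTCCTAGGGACCCCCCATTGTATGTTAACAGCCGC
TGGACCTTGTAGTGTTGTATTACACGGAGTATTAAACTCCCGAGGGTCCCTGCGACGTGACTTAGTGGAC
CTTGCTTATGGACCACTACAGATGAAAGAGCAATTCTCTGGAATCGGTCCATGGCGGTAACACGGCTTAG
ACGGAGGGAGGAATAAACCGTCTTCTCTCATTGGCATATCCATTATGCAATCGGGGCATGCAATCCATAC
ATAGTTAAGATCAGAGCTTCTCTATTGTACAGACGATACTGCCTTCCCCTGTGCAATTTTGGTTTGGCCA
GTAACGCCTGCCGCCCTAAAGGTAACCAGTAAGGGCGGCCTCCTACTTGTGTCTAGGTTCAAGACCATCC
GGGGTTTGAGGAGATAAGTATATTGCACACCCAACCCAATTACGCCGTGTGGTATCTACCCTTATTGGGC
TTACTAGTTGTAAGATTTGTTCTAGATGTAGGTGTTCCAATTATGCTTTTT
>CYP2D7_INT2_synthetic synthetic pseudogene intron-2 stand-in at ~93% identity to the gene stand-in (generated, not a GenBank record)
TTCAATCTAACAGAGCCCTCATGGCGTAAATTGGATATGAATAGAAACTTTGTTCACGTGTTATGCGCGA
TTTCCCGAAGGAGAACAGGAGGAACCACGTAAAACATGGAGTTAGGGTCGTATGCAATTAGGTACGTATT
CGATTGCTTCGGACGGTTGGCAGTGGGTGGACGCAAACCCTAGCCCCGCATAACGCGTGGGATCTGTCCT
TTAAAATGAAATGAAGGGGCTGTCGGATCTACCTGCCAGCATATGACAAGTCTGAAGTTACCGCCAGTCT
GCCTACAGAAACCAACACGTGTACACAGCATGTTAAGTTATAGGACATAACGGACTTCGTACGGGCAGGG
ATATATGTCTACGGTTCACCAAGAACGCACTAATGCTGATTTAAGACCTTGCATATTGTGGCTACAAGGT
GGGTTGGACGAGGCTAGTGCTTAATTCCGGGTTACATGGGAGTATCTTTATAATTGCTGTAGTAATAACA
TCAACTGAGTAGGGCATTCGAGGTGCACTCCTGAAGGGGACACAGCACTGTGGTACCGTGGACGACACAG
GCATTCGACATGATGAAGATTGCCGTGTATTACCAATCCTAGGGACCCCCCATTCTATGTTAACAGCCGC
TGGACCTTGTAATGTTGTATTACACTGAGTCTTAAACTCCCGAGGGTCCGCGCGACGTGACTTAGTGGAC
CTGGCTTATGGACCACTACAGATGAAAGAGCAATTCTCTGGACTCGGTCCATGGGGGGAACACGGCTTAG
ACGGAGGGAGGAATAAACCGCCTTCTCTGATTGGCATATCCATTATGCAATCGGGGCATGAAATCCATAC
TTAGTTAAGATCACGCCTTGTCTATTGTACAGCCGATACTGCCTTCCCCTCTGCAATTTTGTTTTTGCCA
GTAACGTCTGCCACCCTAAAGGTAACCAGTAAGGGCCGCCTCCTACTTGTGTCTATGTACAAGACCATCC
GGGGTTTGAGCAGATAAGTATATTGCACACCCAACCCAATTACGCCGTGTGGTATCTACCTTTACTGGGC
TTGTTAGTTTTAAGATTTGTTCTAGATGTAGATGTTCCAATTATGCTTTTT
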