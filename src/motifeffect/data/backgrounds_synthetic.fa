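>synthetic_bg_0
CTGAAGCGGCCGGATCCTTCCAAATTGACTACCACTGACCCGAAGCTGACAGCCCGCTAGGATCCTTTCTATAAACGCTCCACCAGCGACGAGCGAACAA
>synthetic_bg_1
TGAGTGTTGATTCGTACATACAACGTCCCGCCCTTCGCTGGAAGCCCCCGCAGACCTTGCACCGGCGCCGGTACGCGGAGTAGCGCTATTAGGCCTGATC
>synthetic_bg_2
AGTGTGGGGCGACCGCGACCTACTGTTGTCATGGGGCTCCACTAAGGATCGATACAGTGCCGGCGGGTACGATATGTACACGCGCGTCTATCGGACACTT
>synthetic_bg_3
TCCGTATCTACTGAAGTCAGCAGTTGAACCCTCACGAAGTTATAATATAGACTTTTCATGGATCCAATCGTAGTTCGTCGATCAACCGTCACGCTATGCG
>synthetic_bg_4
GACGAATAAAGCCTGAATATACGGGCGTGAACCGTGAAGGGATGAAGATTCGCAATCTAACAGGAGCAGAGACACTAGATTCCGAGCGGCGTTCGGCGAT
>synthetic_bg_5
TACAAGAATCTCTACCCAGCTTTGCTACCCTCATCCGGATCCCGGAAAGCGAATGGCGCAAACTTCTTAAGAGATTTTGCCGAGTCGGTGCCTCGTTGCA
>synthetic_bg_6
ACTAACTATGCAGAGGCGACATGATAATCCTCGCAAGCGCCATATTACCTTGTACTCCTCTACTACGACGAGGGTCAATTCCCCGGCTTTCGTAGGATAA
>synthetic_bg_7
CGCAGGCACCCTTCCCGCCCCGTGTTGTATCTCAACTACGAACATTACCACGGATACAATCATCACCGCCATGTTAATAGATACCTACGATTAGCGTCCT
>synthetic_bg_8
CGAACTTCGAAGGATGCCGCCAATAGAGCCAGTGGACACGTGATCCTAGCCGTCCTGATATGTTTAACCTCCCCGAAGGCTAGTTCGGTGGCACCACCAA
>synthetic_bg_9
ATACGCATGGGCAGTCCTTGTCTGGCGCAAAAGGTAGGTGAAATTAACGGTGACCCTGAATGCACAAAAGATTAGTGTAAGCTGCATTATCCCAAGTCTG
>synthetic_bg_10
TATAGGTTATTAAAATCACTTACACGTGGGCATCCTTTGATCTGGGTAAACACCTCTCGCAGTCTGATGCCCCTCCTGGGCAGGTAGTTCTAGCTCGTCG
>synthetic_bg_11
GTTTTTCTAACTGATCACCTAGGGGAGATACGTGGTCAGGGACGCGTGCGACGCAAGCTCCCCCCCGACCAGGCGATCCGACAGGCGGGCGTAGACCTCA
>synthetic_bg_12
CTCGAACGGTCGTATCGAAGTGGTAGTACGAAATCGATCTTACCGGTCATAACCTGGATCTATCGTTCCGCGAGATGGCCCAACTGACATGTCTGTCAAA
>synthetic_bg_13
CGATAAACGGGTTGTAGTAGAGGATGTTCAAACTAGGCTAAGGCAAACTTGCCACCAGAGTTCGGCTTCCTTTTAATGTCTTTCACTTCCCCGACAGAGA
>synthetic_bg_14
ATGGCGTCGACTTATGAGGATTAAACATTAGAGAGGACCACGGACACAAAACTTAGATGGTTCTCGTGCTACTCTACAGCAGTGAAGGCTTGGCCTCCGC
>synthetic_bg_15
CTAGCAACTACCCAAAAGAGGTTGCTAGAGCCTCGGCAGTAACAGTAGACTGCTAATACAGCGAAGTGGGGCGACATAGATTAATGTGCCAACACCACGA
>synthetic_bg_16
AACACCGAGCGCTTTGATCAATGGTCAGGGATGGTAACGCACCTCTCTTTACAAGGATGATGTGTCCCCGCGTGCGGAGCAAGTGAAGATCGGCTGAAGC
>synthetic_bg_17
TAGCGGAGTAACAACTTGGCCGGTTTCCGGATCCCCTCTGCGGCTTCGATTTCTTTTACTCCGAATCCGATTGGTCCTCTTCAGCCTATGTGGCGAGGCC
>synthetic_bg_18
CATGGTATTAGTAGCACTCCTAGCAATGCTGCGCCTATTCGCTAGCAGGCGGAACCGTAGTATAATCTGCAGACTAAATTCAAGACTTACAACGAGTAAC
>synthetic_bg_19
AAATGACACTTGCGCCAGAATACGGACACGACAAGGGACACGACAACCGAATAAAGACGCTACAGAAATTTCAACACACAGCAATATTGAACGCCAGTGG
>synthetic_bg_20
CGGGCCGCGTCATGTCCATAACTAGGACGGCTAACTGTGCTACGAGCCCGGGGGTAGGGGGGATGCAAATTCCTGCGGGTCAAAAAGTGCTAGCTCCCGT
>synthetic_bg_21
CTGATCTGCTATGGTCCAACCCAGTTATCTGAACTCGCAATAACAGGCTTGCGTCAGAAACCCTCACACTACAGCCGTGTTGGTGTGAAGCGGCATGGCG
>synthetic_bg_22
GTCAGTATAAATCCCCTTCACAAAAATCGTTTCCATTGTCGTGAAAGATGTAATACCCATCTGATCCCACGTATGACGACCTTCCGGTAGTGAAACCCGG
>synthetic_bg_23
TCTAGCGCGAGATTATGCTTGCGCGGCACTAGGCTATTGAGGCCCATATGCCGGCGTCGTGGATTAGTAGCTTGCCCCCTTCAATTGCCAAGCTGTATGT
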