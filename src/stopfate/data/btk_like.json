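{
"transcript_id": "BTK_LIKE",
"exon_lengths": [
80,
80,
80,
80,
80,
80,
80,
120,
120,
120,
120,
120,
120,
120,
120,
120,
120,
120,
160
],
"cds_start_tx": 1,
"cds_end_tx": 1980,
"spliced_seq": "ATGTTGCCACCTCCGGGGTCAACCGGGCTTTCCTACGTACGAGTCGGGCGGGCTTTTAAAAGTAGCCGATTCTTACACAAGATCTCTATCACCCGGGCATACGGGACGTCTACATTCAAATTATTGCACGAAGTTAGTCCGCGTAAGAATAAGGTTGGGTTCACAGTTTCCCTTACAAACCGGATCAAGATGCTGTCGAAGCGACCGTCGCTGCCCAGGAAGTGGCATAATGTATTGAGTAACAGCTACTGTCCTGTTCGTGGTTGGGTCCGCCTGGCGTATTACCCCTCCAGTTGCCGTATACGGTCTAATTTAAACGACGGGGAGCTGCGCACTTACCCCCCTCGTTTTCATAGAGGACAGTTGTCCAAAAAATGCGCACTTTCCCTGCCTGGAGAGGGTGCGGGAGAGCTAGAACCTACTCGTGAGAAAACTGTCGCAGGGCAGAAGATGAGTACTTCTAGACCCCTACAGCTGTCTACGGCCGCGCTTAAGCCGACAAATAGGATTGCAGACATTTGGGACGCAGAAAACCGACAGGCCGAATTCTCACTACGGAACTGCTTAATGTTGGCCGCGAACTCCGTCGCGCTAAAATGCTCAGTACGCTCCCTGACCACCCTCACAAATCTGATCCAGAGCGACGTCGGTAGCGAGACCCGACTCTGGTTTAACTCGGAGACAGGCTCGAGTGGACGACCCAAATGGGACCGGTTCATCCTGGGCTCAGCCCTGCTCACACGTCGAAGCAAATCTCCGCTATTCAATACTGAGCCTACGGCACCCGCGCGAAGAACCACTGGCGCTCAGTACGCGACTGGTAGCTGGTTCCGGCCGCCCACATCCGTTAATAACGAAGGCTTTCAGTTTAGTTCGATAACCGAACTAAACCCGAGAAAATGTAGCAATGGCCAGACCAGACCCCCCTGGGTAATTTCCTTGCCGCGCTCTGCTATCTCTCGGCAAGTAAAAAATCGGTATAATCTGGGGCTAAGTTGTTGCGGAGATTGCTTGGGTCAACAACGTGTTACTTTCGTTGGAGATAACGTCCAACGTGGCCGCCAGGACTACGTAGAATATATGGCAGACGTCACTCCCCCGCAATTGTTTACCCAACACTCAGGGAGGGCAGCCTGCAAGGACGACCAATGGCCTGGCTGTAAATGCCCCATCTACAGTGCCTTAGCGATAGTCCTGACTGACTTGACCGATACCGGAGATGCAAAATACTATCGTCAATCCGCAAGTTTTCAGCATATGAGCAACGTTGCATATATTCGCCCATTTGAAATCTTCCTTGTAGTTTGGCTCTCAACTGGAAGATTGGGAGAACGCTCTAGTGGACTATTACCCAAGTGCCTAAGATTGGCTGCCGAAGGCGGAGTACTGCAGGCGCCTGGATTTTTGGAAACATGGACCACATTATCTTCGATAGGAATATGCCGTTTCGTGCGTAGGTCCGGAACCGAGGAAAAAACTGCATGCTACTCATTGTATGGGGACTCAGAACCAGGCCAAGGCTACGATTATTCGCCTCTTAGAGTGGGGACTACCTATTTCCATCAGGATGCTGCGGCGGTGCCAGTACAGGGCATCCGCGGCGACTGGTCGATGCAAGGTCAGTTATACCAGTCAAAGTTTACGGTACACGATCGTCACAGCTTTGTCAACAATCGCAATATACAACCGGTACCTCGCGGATACGAAGAAGAGCAAGTAGTCCCTCAGGGGGTTAAGACTCACGGTATCACGCTCTTTGACTTGACATCACGGCAGGCTATCGAACGCGCCTTACTCTGCTTTAGAAAGGTACTGCCTGGTGTAACTAGTCGGGGGGGCAAAACCCTCAGTGCACTGAGTGATAGCCGCCGGTGCCTAGTGCCCAGGATAAGGAACGCGAGCGGTGCCCGTTTGAGTGAAGCTGCTGCCAGCGGTTCTACAGTAATGATCCATAATAGACGTCCCGTAGTGCACTATTAATGACGCCCTCTCGGCTTGAGCTTTTCAACCATTTATGAAAAGTGCGTTACGTATATGCGC"
}
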