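>Tau-miRNA-166 target=E2/3
ACCGGTGTCGACTTTAAAGGGAGGTAGTGAGTGGACCAGTGGATCCTGGAGGCTTGCTGA
AGGCTGTATGCTGAATGCCTGCTTCTTCAGCTTTGTTTTGGCCACTGACTGACAAAGCTG
AAAGCAGGCATTCAGGACACAAGGCCTGTTACTAGCACTCACATGGAACAAATGGCCCAG
ATCTGGCCGCACTCGAGATATCTAGAATTCACTAGTGAGCTC
>Tau-miRNA-724 target=E11
ACCGGTGTCGACTTTAAAGGGAGGTAGTGAGTGGACCAGTGGATCCTGGAGGCTTGCTGA
AGGCTGTATGCTGTAATGAGCCACACTTGGAGGTGTTTTGGCCACTGACTGACACCTCCA
AGTGGCTCATTACAGGACACAAGGCCTGTTACTAGCACTCACATGGAACAAATGGCCCAG
ATCTGGCCGCACTCGAGATATCTAGAATTCACTAGTGAGCTC
>Scr-miRNA scrambled control
accggtGTCGACTTTAAAGGGAGGTAGTGAGTGGACCAGTGGATCCTGGAGGCTTGCTGA
AGGCTGTATGCTGAAATGTACTGCGCGTGGAGACGTTTTGGCCACTGACTGACGTCTCCA
CGCAGTACATTTCAGGACACAAGGCCTGTTACTAGCACTCACATGGAACAAATGGCCCAG
ATCTGGCCGCACTCGAGATATCTAGAATTCACTAGTGAGCTC
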