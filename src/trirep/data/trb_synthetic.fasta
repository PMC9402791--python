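>TRBV1 functional=yes
GCTGTTGAATTTAAGGATATCAATTGTTCTTTTCGAAATCGATCGACGATTTACTATTATTGCGCTAGCTCC
>TRBV2 functional=yes
CATTCTAAACCACATGGGCCCTTAAAATCGAGCGCTTACGCGATAAGTCCAGAATATATATGTGCAAGCAGC
>TRBV3 functional=yes
TATGCGGGTCCTACATCTCATACGACCGTGTTAGTGTCTCCAGTCGGGTTTCACTACTTTTGTGCGAGCTCC
>TRBV4 functional=yes
ACTTGTGTGGCGGCCGTCTGGAACCTTCCAGTCATTGACGGCAATCTTGGATGGTACCTGTGCGCATCCAGC
>TRBV5 functional=yes
TGCCAGAACCCGGCGGCTCATGAGAATATTATTTCCGACAATATTATAGAGTTCTACATATGTGCAAGTTCC
>TRBV6 functional=yes
ATCTTAAGGCTCATAGTAACGGCCGAATCTACGATGCCCGTTAAAATAGTCATGTATTTTTGTGCTAGTTCC
>TRBV7 functional=yes
ATAGCCAATTACAAGAAATTGGGTGAGACAGTATTGCGAGGTGTGAAGGATCTTTACTATTGCGCGTCCAGC
>TRBV8 functional=yes
CCGATGGAGCGCACCCAATCGAACCAAACTTGGAAGACCCGGTTCCCGTGGGCCTACATATGCGCATCCTCC
>TRBV9 functional=yes
CCCGAATTGTACCTACGTAGATGCCCTACACTATACAGTGGACGATATGTGAGCTATCTGTGTGCGTCCAGT
>TRBV10 functional=yes
GCCGGTTCCAGAACTTCCTCATCAACACGCCAGATGCTTTGGGCTCAGCTCCTCTATCTGTGCGCTAGCAGT
>TRBV11 functional=yes
CCACGGGCCAAACGGGACGCTTTTCCGTTCGCCGGGGCATTCAAGCCTTTGTCATACTATTGCGCTTCAAGC
>TRBV12 functional=yes
TACTTGCTATGTCCCTCGACCATATGGCGGAATAACTCACCTCCGGTGTGGAGATATTATTGCGCATCATCA
>TRBJ1 functional=yes
TTGGTATTACCAGCACCTTGGGGTAACGGTACGCAAACACAGCCGGCA
>TRBJ2 functional=yes
TCGAGCTTCCTGAAGAATTGGGGCGTCGGCACTCAAAAGGTACTGGAG
>TRBJ3 functional=yes
GCCGTTCTATCGATCGTATGGGGTCTCGGTACTCCTAGTTTTGGAACT
>TRBJ4 functional=yes
TCCGAGTACACTGAATACTTCGGGTTCGGTACCCGTTCCAATCGAGGG
>TRBJ5 functional=yes
GAGAGATGCAAGTTTTGCTGGGGCCCAGGAACATTAGGAGACGCCGGA
>TRBJ6 functional=yes
AGTCTTGCCAGACCGTTCTGGGGCCAGGGCACCTCCGAGATTGACTTC
>TRBC1 functional=yes
AAGCACGTGCACAAATGTACGTCAAGAGAG
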