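>TRBV1 type=V locus=TRB anchor=45
TCAACACAATGGAATAACCCCAGCCCAGGGCAAGGCAGCACTCCGTGTGCCAGCAGCCAAGAA
>TRBV13-1 type=V locus=TRB anchor=45
TAAGCGACGGAGCAGTCCACCCATTTATTGGCACGCGGTCTCCCTTGTGCCAGCAGTGATGCA
>TRBV13-2 type=V locus=TRB anchor=45
TCCGATGACACCAACGGCTCCGCCCATCGGGTTTATTGGGTTTTGTGTGCCAGCGGTGATGCA
>TRBV13-3 type=V locus=TRB anchor=45
TGCAGGACTGCGAGGAACAAACGTTCTCTGCGACTAGGAGGTTGATGTGCCAGCAGTGGTGCA
>TRBV19 type=V locus=TRB anchor=45
CCGTGGCGAGATCCCGTGAAGATAAACCTAGAAGATTGGATCATCTGTGCCAGCTCTACAGGG
>TRBV29 type=V locus=TRB anchor=45
AGAGTGAACATGACCAGGCCCTATCGAGTTGTTATGGGTTCTAGATGTGCCAGCAGTTTAGGG
>TRBVother type=V locus=TRB anchor=45
TTTACAGCGCTGGATGACTATGCGACTCTCCCGATTCTGGTTATCTGTGCCTGGAGTCTAGCA
>TRAV11 type=V locus=TRA anchor=45
AAGGTATCGCGTTATTCGCATGCTTTCGCCAGATGAAGGTATTTATGTGTGGTGGGG
>TRAV9 type=V locus=TRA anchor=45
ATTCGCTAAATGTAGTACTGTCGAGAGAGAGAAAACCATGGGTGGTGTGCTGTGAGT
>TRBJ1-1 type=J locus=TRB anchor=18
AATACCGAAGCGTTGTACTTCGGGACAGGGACCAAG
>TRBJ2-5 type=J locus=TRB anchor=18
AACCAGGACACCCAGTACTTTGGTCCAGGGACACGG
>TRBJ2-7 type=J locus=TRB anchor=18
AGCTACGAGCAGTACGTCTTCGGCGCAGGCACCCGG
>TRAJ18 type=J locus=TRA anchor=30
GACAGAGGGTCAGCCTTAGGGAGATTACACTTTGGAACAGGAAAG
>TRAJ12 type=J locus=TRA anchor=21
GGTACTGGAAGTAAGCTCTCATTTGGAGATGGAACT
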