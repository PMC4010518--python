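>NM_006766.3 KAT6A
GATGTACTCAGGTGTCAGTCCTCTTCTAAGAGGAAGTCTAAAGATGAAGAAGAAGATGAAGAGTCAGATG
ATGCTGATG
>NM_004380.2 CREBBP
AGAACTTGCTGGACGGACCGCCCAACCCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGA
CAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGA
GAATTAGGCCTTTTAAACAGTGGGAACCT
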