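>read01
CCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGAT
>read02
CGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAACAGT
>read03
AAGAAGAAGATGAAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTA
>read04
ACTTGCTGGACGGACCGCCCAACCCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAA
>read05
ATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAAGATCGGAAGAGCGTCGTGTAGGG
>read06
GTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAACAGTG
>read07
AAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAAC
>read08
AGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAACA
>read09
AGAACTTGCTGGACGGACCGCCCAACCCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTG
>read10
GACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAACAGTGGGAACCT
>read11
AACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGTAGGA
>read12
CTGGACGGACCGCCCAACCCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGA
>read13
AGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCAGATC
>read14
GAAGATGAAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGGCAGATCGGAAG
>read15
GCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGG
>read16
CTCAGGTGTCAGTCCTCTTCTAAGAGGAAGTCTAAAGATGAAGAAGAAGATGAAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAA
>read17
CTTGCTGGACGGACCGCCCAACCCCAAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAA
>read18
AAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCC
>read19
CAGTCCTCTTCTAAGAGGAAGTCTAAAGATGAAGAAGAAGATGAAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCC
>read20
GCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGG
>read21
AAAAGAGCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACC
>read22
GCCAAACTCAGCTCGCCCGGTTTCTCGGCGAATGACAGCACAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAGATC
>read23
GATGTACTCAGGTGTCAGTCCTCTTCTAAGAGGAAGTCTAAAGATGAAGAAGAAGATGAAGAGTCAGATGATGCTGATGATTTTGGATCATTGTTTGACTT
>read24
ATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGAGATCGGAAGAGCGTCGTG
>read25
GTAAAGGTTGCTTAGTTTCTCATTTCCATTTCTGTTTAATTTCTAGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAA
>read26
GATGATGCTGATGATTTTGGATCATTGTTTGACTTGGAAAATGATCTTCCTGATGAGCTGATACCCAATGGAGGAGAATTAGGCCTTTTAAACAGTGGGAA
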