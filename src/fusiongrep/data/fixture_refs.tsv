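accession	gene	coord_offset	exon_label	exon_start	exon_end	cds_start	cytoband
NM_006766.3	KAT6A	3686	16	3686	3764		8p11
NM_004380.2	CREBBP	212	1	212	289		16p13
NM_004380.2	CREBBP	212	2	290	380		16p13
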