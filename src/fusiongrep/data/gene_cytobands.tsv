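gene	cytoband
KAT6A	8p11
MYST3	8p11
MOZ	8p11
CREBBP	16p13
CBP	16p13
DTX3L	3q21
SLK	10q24
DNAJC14	12q13
TTC28	22q12
RBM15	1p13
MKL1	22q13
RUNX1	21q22
RUNX1T1	8q21
ERG	21q22
FUS	16p11
CBFB	16p13
MYH11	16p13
GLIS2	16p13
CBFA2T3	16q24
FGFR1	8p11
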