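"""Audit a genome-wide fusion caller's candidate list against a karyotype.

A caller can emit hundreds of candidates yet miss the pathogenetically
relevant fusion.  Given the caller table, a gene->cytoband map and the
karyotype breakpoint bands, this audit answers: was the suspected pair
called at all (under symbol aliases), which candidates are even compatible
with the observed breakpoints, and what translocation would each imply.
"""

import tempfile
from pathlib import Path

from fusiongrep import audit_target_pair, cytoband_filter, iscn_translocation, parse_caller_table
from fusiongrep.audit import load_gene_loci
from fusiongrep.data import gene_cytobands_path

# a miniature caller output in the style of a FusionMap candidate table
table = """FusionGene\tRank\tSeedCount
DTX3L-MYST3\t91\t14
MYST3-SLK\t193\t9
CREBBP-TTC28\t401\t5
MYST3-DNAJC14\t606\t3
"""
with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "caller_calls.tsv"
    path.write_text(table)
    records = parse_caller_table(path, {"pair": "FusionGene", "rank": "Rank"})

aliases = {"MYST3": "KAT6A", "MOZ": "KAT6A", "CBP": "CREBBP"}
loci = load_gene_loci(gene_cytobands_path())

present, rank = audit_target_pair(records, "KAT6A", "CREBBP", aliases)
print(f"caller candidates: {len(records)}")
print(f"target KAT6A-CREBBP present: {present} (rank: {rank})")

bands = {"1p13", "8p11", "16p13", "21q22"}  # karyotype breakpoints
kept, dropped = cytoband_filter(records, loci, bands, "any", aliases)
print(f"candidates touching karyotype bands {sorted(bands)}: {len(kept)} "
      f"({dropped} unresolvable dropped)")
for rec in kept:
    a = loci[aliases.get(rec.gene5.upper(), rec.gene5.upper())]
    b = loci[aliases.get(rec.gene3.upper(), rec.gene3.upper())]
    print(f"  rank {rec.rank:>3}  {rec.gene5}-{rec.gene3}  would imply {iscn_translocation(a, b)}")
print(
    "meaning: none of the retained candidates implies a translocation seen in\n"
    "the karyotype, and the suspected pair is absent - grounds to fall back\n"
    "on targeted anchor retrieval rather than trust the caller's list."
)
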