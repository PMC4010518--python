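"""Rebuild the packaged partial references from the packaged reads.

The 26 published junction-region reads are the only sequence source the
package ships.  This script reconstructs, by per-column majority consensus:

* a partial CREBBP mRNA reference (NM_004380.2 numbering) from the full
  bodies of the wild-type reads, covering 212-380;
* a partial KAT6A mRNA reference (NM_006766.3 numbering) from the upstream
  flanks of the fusion reads right-justified at the breakpoint, covering
  3686-3764.

The outputs are committed as package data; rerunning this script must be a
no-op (the test-suite checks consensus reconstruction independently).

Usage:  python scripts/build_fixtures.py
"""

from __future__ import annotations

import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from Bio import SeqIO

from fusiongrep.data import CREBBP_ACCESSION, KAT6A_ACCESSION, published_reads_path, published_annotations_path
from fusiongrep.references import ExonBound, TranscriptReference, consensus_from_anchored_reads, write_reference
from fusiongrep.retrieval import DEFAULT_ANCHOR, DEFAULT_ACCEPTOR_START


def main() -> None:
    reads = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(published_reads_path()), "fasta")}
    with open(published_annotations_path(), newline="") as fh:
        truth = {row["read_id"]: row for row in csv.DictReader(fh, delimiter="\t")}

    wildtype = [
        (seq, seq.index(DEFAULT_ANCHOR))
        for rid, seq in reads.items()
        if truth[rid]["category"] == "WILDTYPE"
    ]
    fusion = [
        (seq, seq.index(DEFAULT_ANCHOR))
        for rid, seq in reads.items()
        if truth[rid]["category"] == "FUSION"
    ]

    crebbp_cons = consensus_from_anchored_reads(wildtype, "full", DEFAULT_ACCEPTOR_START)
    # the donor breakpoint: fusion upstream flanks end at KAT6A nt 3764, so
    # right-justify them as if the anchor began at 3765
    kat6a_cons = consensus_from_anchored_reads(fusion, "upstream_of_anchor", 3765)

    print(f"CREBBP consensus: {crebbp_cons.coord_offset}-"
          f"{crebbp_cons.coord_offset + len(crebbp_cons.sequence) - 1}, "
          f"{len(crebbp_cons.low_confidence)} low-confidence columns")
    print(f"KAT6A  consensus: {kat6a_cons.coord_offset}-"
          f"{kat6a_cons.coord_offset + len(kat6a_cons.sequence) - 1}, "
          f"{len(kat6a_cons.low_confidence)} low-confidence columns")

    crebbp_end = crebbp_cons.coord_offset + len(crebbp_cons.sequence) - 1
    crebbp = TranscriptReference(
        accession=CREBBP_ACCESSION,
        gene_symbol="CREBBP",
        sequence=crebbp_cons.sequence,
        coord_offset=crebbp_cons.coord_offset,
        # exon intervals clipped to the reconstructed window; only the
        # exon1|exon2 boundary at 289|290 is load-bearing
        exon_bounds=[
            ExonBound("1", crebbp_cons.coord_offset, DEFAULT_ACCEPTOR_START - 1),
            ExonBound("2", DEFAULT_ACCEPTOR_START, crebbp_end),
        ],
        cytoband="16p13",
    )
    kat6a_end = kat6a_cons.coord_offset + len(kat6a_cons.sequence) - 1
    kat6a = TranscriptReference(
        accession=KAT6A_ACCESSION,
        gene_symbol="KAT6A",
        sequence=kat6a_cons.sequence,
        coord_offset=kat6a_cons.coord_offset,
        exon_bounds=[ExonBound("16", kat6a_cons.coord_offset, kat6a_end)],
        cytoband="8p11",
    )

    data = Path(__file__).resolve().parents[1] / "src" / "fusiongrep" / "data"
    write_reference([kat6a, crebbp], data / "fixture_refs.fasta", data / "fixture_refs.tsv")
    print(f"wrote {data / 'fixture_refs.fasta'} and {data / 'fixture_refs.tsv'}")


if __name__ == "__main__":
    main()
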