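"""Accessors for the data files shipped with the package.

The package bundles, as plain text:

* ``published_reads.fasta`` — the 26 published junction-region read sequences
  (101 nt each) that contain the CREBBP exon-2 anchor;
* ``published_read_annotations.tsv`` — their published per-read annotations (category and
  coordinate spans), used as expected values by the test-suite;
* ``fixture_refs.fasta`` / ``fixture_refs.tsv`` — partial KAT6A and CREBBP
  mRNA references reconstructed once from those reads by majority consensus
  (see ``scripts/build_fixtures.py``); they cover KAT6A 3686-3764 and CREBBP
  212-380 in the numbering of NM_006766.3 / NM_004380.2;
* ``gene_cytobands.tsv`` — a small gene -> cytoband table for the audit
  module.

Full mRNA references are optional user-supplied inputs; nothing here
requires network access.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .references import TranscriptReference, load_reference

KAT6A_ACCESSION = "NM_006766.3"
CREBBP_ACCESSION = "NM_004380.2"

__all__ = [
    "published_reads_path",
    "published_annotations_path",
    "fixture_fasta_path",
    "fixture_annotation_path",
    "gene_cytobands_path",
    "load_fixture_references",
    "load_full_references",
    "KAT6A_ACCESSION",
    "CREBBP_ACCESSION",
]


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("fusiongrep") / "data" / name) as p:
        return Path(p)


def published_reads_path() -> Path:
    return _data_path("published_reads.fasta")


def published_annotations_path() -> Path:
    return _data_path("published_read_annotations.tsv")


def fixture_fasta_path() -> Path:
    return _data_path("fixture_refs.fasta")


def fixture_annotation_path() -> Path:
    return _data_path("fixture_refs.tsv")


def gene_cytobands_path() -> Path:
    return _data_path("gene_cytobands.tsv")


def load_fixture_references() -> tuple[TranscriptReference, TranscriptReference]:
    """(KAT6A partial reference, CREBBP partial reference)."""
    refs = load_reference(fixture_fasta_path(), fixture_annotation_path())
    return refs[KAT6A_ACCESSION], refs[CREBBP_ACCESSION]


def load_full_references(search_dir: str | Path = "data/reference") -> tuple[TranscriptReference, TranscriptReference]:
    """(full KAT6A mRNA, full CREBBP mRNA) from user-supplied files.

    The complete NM_006766.3 / NM_004380.2 sequences are not redistributed
    with the package; place them (one-time download from RefSeq) as
    ``full_refs.fasta`` + ``full_refs.tsv`` (same annotation format as the
    fixtures, including ``cds_start``) under ``search_dir``.
    """
    search_dir = Path(search_dir)
    fasta = search_dir / "full_refs.fasta"
    annot = search_dir / "full_refs.tsv"
    if not (fasta.exists() and annot.exists()):
        raise FileNotFoundError(
            f"full mRNA references not found under {search_dir}/: supply "
            f"full_refs.fasta and full_refs.tsv with the complete "
            f"{KAT6A_ACCESSION} and {CREBBP_ACCESSION} sequences, their exon "
            f"tables and cds_start (one-time RefSeq download)"
        )
    refs = load_reference(fasta, annot)
    missing = {KAT6A_ACCESSION, CREBBP_ACCESSION} - set(refs)
    if missing:
        raise ValueError(f"{fasta}: missing accessions {sorted(missing)}")
    for acc in (KAT6A_ACCESSION, CREBBP_ACCESSION):
        if refs[acc].cds_start is None:
            raise ValueError(f"{annot}: cds_start required for {acc}")
    return refs[KAT6A_ACCESSION], refs[CREBBP_ACCESSION]
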