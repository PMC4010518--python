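"""Anchor k-mer retrieval: the grep step.

A fusion whose acceptor-side breakpoint is known can be hunted in raw reads
with a literal string search for the first bases of the acceptor's first
fused exon (here the first 20 nt of CREBBP exon 2).  Every read containing
that anchor — fusion, wild-type acceptor transcript, or anything else that
happens to carry the exon — is retrieved; classification happens downstream.

The search is exact by design: a single substitution inside the anchor hides
a read, which is precisely the sensitivity limitation the simulator
quantifies.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .references import VALID_BASES

DEFAULT_ANCHOR = "ATTTTGGATCATTGTTTGAC"  # first 20 nt of CREBBP exon 2
DEFAULT_ACCEPTOR_ACCESSION = "NM_004380.2"
DEFAULT_ACCEPTOR_START = 290  # mRNA coordinate of the anchor's first base

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "AnchorSpec",
    "SequencedRead",
    "AnchoredRead",
    "scan_reads",
    "grep_equivalence_check",
    "read_sequences",
    "write_anchored_tsv",
    "write_anchored_fasta",
    "revcomp",
    "DEFAULT_ANCHOR",
    "DEFAULT_ACCEPTOR_ACCESSION",
    "DEFAULT_ACCEPTOR_START",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchorSpec:
    """The anchor k-mer and where it sits on the acceptor mRNA."""

    anchor: str = DEFAULT_ANCHOR
    acceptor_accession: str = DEFAULT_ACCEPTOR_ACCESSION
    acceptor_start: int = DEFAULT_ACCEPTOR_START
    search_revcomp: bool = False

    def __post_init__(self) -> None:
        if len(self.anchor) < 12:
            raise ValueError("anchor must be at least 12 nt (specificity)")
        bad = set(self.anchor) - (VALID_BASES - {"N"})
        if bad:
            raise ValueError(f"anchor contains non-ACGT characters {sorted(bad)}")
        if self.acceptor_start < 1:
            raise ValueError("acceptor_start must be a 1-based mRNA coordinate")

    @property
    def acceptor_end(self) -> int:
        return self.acceptor_start + len(self.anchor) - 1


@dataclass(frozen=True)
class SequencedRead:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality length != sequence length")


@dataclass(frozen=True)
class AnchoredRead:
    """A retrieved read, oriented so the anchor reads in acceptor sense."""

    read: SequencedRead
    anchor_offset: int
    orientation: str  # 'forward' | 'revcomp'
    oriented_sequence: str
    multiple_hits: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "revcomp"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0 <= self.anchor_offset < len(self.oriented_sequence):
            raise ValueError(f"{self.read.read_id}: anchor_offset out of range")


def scan_reads(reads: Iterable[SequencedRead], spec: AnchorSpec) -> Iterator[AnchoredRead]:
    """Yield one AnchoredRead per read containing the anchor exactly.

    Forward orientation is always searched and wins when present; the reverse
    complement is searched only when ``spec.search_revcomp``.  On multiple
    occurrences the leftmost is used and ``multiple_hits`` is set.  Input
    order is preserved; reads without the anchor are dropped.
    """
    anchor = spec.anchor
    for read in reads:
        seq = read.sequence.upper()
        offset = seq.find(anchor)
        if offset >= 0:
            more = seq.find(anchor, offset + 1) >= 0
            yield AnchoredRead(read, offset, "forward", seq, more)
            continue
        if spec.search_revcomp:
            rc = revcomp(seq)
            offset = rc.find(anchor)
            if offset >= 0:
                more = rc.find(anchor, offset + 1) >= 0
                yield AnchoredRead(read, offset, "revcomp", rc, more)


def grep_equivalence_check(reads: Iterable[SequencedRead], spec: AnchorSpec) -> bool:
    """Regression guard: forward-only scan selects exactly the reads a naive
    literal substring search selects."""
    reads = list(reads)
    fwd_spec = AnchorSpec(spec.anchor, spec.acceptor_accession, spec.acceptor_start, False)
    scanned = {ar.read.read_id for ar in scan_reads(reads, fwd_spec)}
    naive = {r.read_id for r in reads if spec.anchor in r.sequence.upper()}
    return scanned == naive


def _open_maybe_gz(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[SequencedRead]:
    """Stream reads from FASTA or FASTQ (optionally gzipped).

    Format is inferred from the file name unless given explicitly
    ('fasta' | 'fastq').
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        if stem.endswith((".fq", ".fastq")):
            fmt = "fastq"
        elif stem.endswith((".fa", ".fasta", ".fna")):
            fmt = "fasta"
        else:
            raise ValueError(f"cannot infer read format from {path.name}; pass fmt=")
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SequencedRead(rec.id, str(rec.seq).upper(), qual)


def write_anchored_tsv(anchored: Iterable[AnchoredRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\torientation\tanchor_offset\tmultiple_hits\toriented_sequence\n")
        for ar in anchored:
            fh.write(
                f"{ar.read.read_id}\t{ar.orientation}\t{ar.anchor_offset}\t"
                f"{int(ar.multiple_hits)}\t{ar.oriented_sequence}\n"
            )
            n += 1
    return n


def write_anchored_fasta(anchored: Iterable[AnchoredRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for ar in anchored:
            fh.write(f">{ar.read.read_id} {ar.orientation} offset={ar.anchor_offset}\n")
            fh.write(ar.oriented_sequence + "\n")
            n += 1
    return n
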