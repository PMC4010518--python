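"""Transcript references in mRNA coordinates.

Everything in this package works in 1-based inclusive mRNA coordinates of an
accessioned transcript (e.g. NM_006766.3 for the KAT6A mRNA); there are no
genomic coordinates anywhere.  A :class:`TranscriptReference` may store only a
window of the full mRNA (``coord_offset`` > 1): the packaged fixtures are
partial references reconstructed by majority consensus from published
junction-region reads and cover just the neighbourhood of the fusion
breakpoint.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "TranscriptReference",
    "GeneLocus",
    "ExonBound",
    "ConsensusResult",
    "load_reference",
    "write_reference",
    "subseq",
    "consensus_from_anchored_reads",
    "build_fusion_transcript",
]


@dataclass(frozen=True)
class ExonBound:
    """One exon interval in 1-based inclusive mRNA coordinates."""

    label: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneLocus:
    """A gene symbol mapped to its cytogenetic band, e.g. KAT6A -> 8p11."""

    gene_symbol: str
    cytoband: str

    def parse_band(self) -> tuple[str, str, str]:
        """Split the cytoband into (chromosome, arm, band), e.g. 16p13 ->
        ('16', 'p', '13').  Raises ValueError on malformed bands."""
        band = self.cytoband.strip()
        for i, ch in enumerate(band):
            if ch in "pq":
                chrom, arm, pos = band[:i], ch, band[i + 1 :]
                if chrom in _CHROMS and pos:
                    return chrom, arm, pos
                break
        raise ValueError(f"unparseable cytoband {self.cytoband!r} for {self.gene_symbol}")


_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


@dataclass
class TranscriptReference:
    """A (possibly partial) mRNA sequence with its exon map and CDS start.

    ``sequence[i]`` is the base at mRNA coordinate ``coord_offset + i``.
    """

    accession: str
    gene_symbol: str
    sequence: str
    coord_offset: int = 1
    exon_bounds: list[ExonBound] = field(default_factory=list)
    cds_start: int | None = None
    cytoband: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"{self.accession}: non-DNA characters {sorted(bad)}")
        if self.coord_offset < 1:
            raise ValueError(f"{self.accession}: coord_offset must be >= 1")
        if self.cds_start is not None and self.cds_start < 1:
            raise ValueError(f"{self.accession}: cds_start must be >= 1")
        self._check_exons()

    def _check_exons(self) -> None:
        prev: ExonBound | None = None
        for ex in self.exon_bounds:
            if ex.start > ex.end:
                raise ValueError(f"{self.accession}: exon {ex.label} has start > end")
            if prev is not None:
                if ex.start <= prev.end:
                    raise ValueError(
                        f"{self.accession}: exon {ex.label} overlaps or is out of "
                        f"order with exon {prev.label}"
                    )
            prev = ex
        if self.exon_bounds:
            w0, w1 = self.window
            if not any(ex.start <= w1 and ex.end >= w0 for ex in self.exon_bounds):
                raise ValueError(
                    f"{self.accession}: no exon interval intersects the stored "
                    f"window {w0}-{w1}"
                )

    @property
    def window(self) -> tuple[int, int]:
        """(first, last) mRNA coordinate covered by the stored sequence."""
        return self.coord_offset, self.coord_offset + len(self.sequence) - 1

    def contains(self, coord: int) -> bool:
        w0, w1 = self.window
        return w0 <= coord <= w1

    def base_at(self, coord: int) -> str:
        return subseq(self, coord, coord)

    def exon_label_for(self, start: int, end: int) -> str:
        """Human-readable exon annotation for a coordinate span, mirroring the
        conventional "exon 16" / "exon 1-2" style."""
        hit = [ex.label for ex in self.exon_bounds if ex.start <= end and ex.end >= start]
        if not hit:
            return ""
        if len(hit) == 1:
            return f"exon {hit[0]}"
        return f"exon {hit[0]}-{hit[-1]}"


def subseq(ref: TranscriptReference, start: int, end: int) -> str:
    """The reference bases from ``start`` to ``end`` (1-based, inclusive)."""
    w0, w1 = ref.window
    if not (w0 <= start <= end <= w1):
        raise ValueError(
            f"{ref.accession}: requested {start}-{end} outside stored window {w0}-{w1}"
        )
    return ref.sequence[start - w0 : end - w0 + 1]


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> dict[str, TranscriptReference]:
    """Load transcript references from a FASTA plus an exon-annotation TSV.

    The TSV has a header ``accession gene coord_offset exon_label exon_start
    exon_end cds_start cytoband`` with one row per exon; ``cds_start`` and
    ``cytoband`` may be blank and are taken from the first non-blank row of
    the accession.
    """
    records = {rec.id.split()[0]: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta: dict[str, dict] = {}
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "gene", "coord_offset", "exon_label", "exon_start", "exon_end"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"annotation {annotation_path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            acc = row["accession"].strip()
            try:
                offset = int(row["coord_offset"])
                ex = ExonBound(row["exon_label"].strip(), int(row["exon_start"]), int(row["exon_end"]))
            except (TypeError, ValueError) as err:
                raise ValueError(f"annotation {annotation_path} line {lineno}: malformed coordinates ({err})") from None
            entry = meta.setdefault(acc, {"gene": row["gene"].strip(), "offset": offset, "exons": [], "cds": None, "band": None})
            if entry["offset"] != offset:
                raise ValueError(f"annotation {annotation_path} line {lineno}: inconsistent coord_offset for {acc}")
            entry["exons"].append(ex)
            cds = (row.get("cds_start") or "").strip()
            if cds and entry["cds"] is None:
                entry["cds"] = int(cds)
            band = (row.get("cytoband") or "").strip()
            if band and entry["band"] is None:
                entry["band"] = band

    refs: dict[str, TranscriptReference] = {}
    for acc, seq in records.items():
        if acc not in meta:
            raise ValueError(f"FASTA record {acc} has no annotation rows in {annotation_path}")
        m = meta[acc]
        refs[acc] = TranscriptReference(
            accession=acc,
            gene_symbol=m["gene"],
            sequence=seq,
            coord_offset=m["offset"],
            exon_bounds=sorted(m["exons"], key=lambda e: e.start),
            cds_start=m["cds"],
            cytoband=m["band"],
        )
    return refs


def write_reference(refs: Iterable[TranscriptReference], fasta_path: str | Path, annotation_path: str | Path) -> None:
    """Inverse of :func:`load_reference`; used to materialise fixtures."""
    refs = list(refs)
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.accession} {ref.gene_symbol}\n")
            for i in range(0, len(ref.sequence), 70):
                fh.write(ref.sequence[i : i + 70] + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("accession\tgene\tcoord_offset\texon_label\texon_start\texon_end\tcds_start\tcytoband\n")
        for ref in refs:
            for ex in ref.exon_bounds:
                cds = "" if ref.cds_start is None else str(ref.cds_start)
                band = ref.cytoband or ""
                fh.write(
                    f"{ref.accession}\t{ref.gene_symbol}\t{ref.coord_offset}\t"
                    f"{ex.label}\t{ex.start}\t{ex.end}\t{cds}\t{band}\n"
                )


@dataclass(frozen=True)
class ConsensusResult:
    """Majority-vote consensus and the mRNA coordinate of its first base.

    ``low_confidence`` lists coordinates where the vote was tied (broken
    lexicographically A<C<G<T).
    """

    sequence: str
    coord_offset: int
    low_confidence: tuple[int, ...] = ()


def consensus_from_anchored_reads(
    reads: Sequence[tuple[str, int]],
    side: str,
    anchor_mrna_start: int,
) -> ConsensusResult:
    """Per-column majority consensus of reads that share a known anchor.

    Each read is a ``(sequence, anchor_offset)`` pair, ``anchor_offset`` the
    0-based index at which the anchor begins inside the read.

    side='full'
        The whole read is projected onto mRNA coordinates so that its anchor
        starts at ``anchor_mrna_start``.
    side='upstream_of_anchor'
        Only the flank before the anchor contributes, right-justified so its
        last base sits at ``anchor_mrna_start - 1``.  This is how a donor-side
        partial reference is rebuilt from junction-spanning reads, whose
        sequence downstream of the junction belongs to the other gene.

    N never votes; ties are broken lexicographically and flagged.
    """
    if side not in ("full", "upstream_of_anchor"):
        raise ValueError(f"unknown side {side!r}")
    if not reads:
        raise ValueError("consensus requires at least one read")

    columns: dict[int, dict[str, int]] = {}
    for seq, offset in reads:
        seq = seq.upper()
        if side == "full":
            start = anchor_mrna_start - offset
            piece = seq
        else:
            piece = seq[:offset]
            start = anchor_mrna_start - len(piece)
        for i, base in enumerate(piece):
            if base == "N":
                continue
            col = columns.setdefault(start + i, {})
            col[base] = col.get(base, 0) + 1

    if not columns:
        raise ValueError("no votes: all reads empty or all-N on the requested side")
    lo, hi = min(columns), max(columns)
    if set(columns) != set(range(lo, hi + 1)):
        raise ValueError("reads do not cover a contiguous coordinate range")

    bases = []
    ties = []
    for coord in range(lo, hi + 1):
        col = columns[coord]
        top = max(col.values())
        winners = sorted(b for b, n in col.items() if n == top)
        bases.append(winners[0])
        if len(winners) > 1:
            ties.append(coord)
    return ConsensusResult("".join(bases), lo, tuple(ties))


def build_fusion_transcript(
    donor: TranscriptReference,
    donor_end: int,
    acceptor: TranscriptReference,
    acceptor_start: int,
) -> str:
    """Chimeric mRNA: donor bases up to the breakpoint joined to acceptor
    bases from the fusion point onward (both inclusive).

    With the stored windows this is
    ``donor[window_start..donor_end] + acceptor[acceptor_start..window_end]``.
    """
    dw0, dw1 = donor.window
    aw0, aw1 = acceptor.window
    if not donor.contains(donor_end):
        raise ValueError(f"donor_end {donor_end} outside {donor.accession} window {dw0}-{dw1}")
    if not acceptor.contains(acceptor_start):
        raise ValueError(f"acceptor_start {acceptor_start} outside {acceptor.accession} window {aw0}-{aw1}")
    return subseq(donor, dw0, donor_end) + subseq(acceptor, acceptor_start, aw1)


def ceil_mismatch_budget(rate: float, length: int) -> int:
    """Maximum tolerated mismatches for a matched stretch of ``length``."""
    return math.ceil(rate * length)
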