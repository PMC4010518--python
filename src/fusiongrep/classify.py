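"""Split-read junction classification.

Every retrieved read carries the anchor (the first bases of the acceptor's
first fused exon).  What identifies its origin is the flank *upstream* of the
anchor:

* it continues the acceptor's own previous exon  -> wild-type transcript;
* it matches a suffix of a donor mRNA            -> fusion junction read,
  and the matched suffix end is the donor breakpoint coordinate;
* it matches neither                             -> something else (e.g. an
  unspliced genomic fragment carrying the exon).

The flank *downstream* of the anchor is always acceptor sequence, possibly
running into the sequencing adapter when the cDNA insert was shorter than
the read (3' read-through), and possibly ending in a few sequencing errors.

Matching is bounded-Hamming (no indels): a flank of length L may carry at
most ceil(max_mismatch_rate * L) substitutions.  N never matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .references import TranscriptReference, ceil_mismatch_budget, subseq
from .retrieval import AnchoredRead, AnchorSpec

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # universal Illumina TruSeq adapter stem

CATEGORIES = ("FUSION", "WILDTYPE", "OTHER", "UNINFORMATIVE", "AMBIGUOUS")

__all__ = [
    "ClassifierParams",
    "ClassifiedRead",
    "JunctionCall",
    "Span",
    "PrefixMatch",
    "match_flank_suffix",
    "match_flank_prefix",
    "classify_read",
    "call_junction",
    "frame_check",
    "write_classified_tsv",
    "write_junction_json",
    "DEFAULT_ADAPTER",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Tolerances of the classifier.

    The defaults (10% per-flank mismatch rate, TruSeq adapter stem with >=5 nt
    overlap, trailing-mismatch trimming, >=6 nt informative upstream flank)
    reproduce the published junction-region read annotations; the shortest
    informative donor flank seen in practice is 9 nt.
    """

    max_mismatch_rate: float = 0.10
    adapter: str = DEFAULT_ADAPTER
    adapter_min_overlap: int = 5
    min_upstream_flank: int = 6
    tie_break: str = "prefer_wildtype"  # or 'ambiguous'

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")
        if self.adapter_min_overlap < 3:
            raise ValueError("adapter_min_overlap must be >= 3")
        if self.min_upstream_flank < 1:
            raise ValueError("min_upstream_flank must be >= 1")
        if self.tie_break not in ("prefer_wildtype", "ambiguous"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass(frozen=True)
class Span:
    """A matched reference interval, 1-based inclusive mRNA coordinates."""

    accession: str
    start: int
    end: int
    exon_label: str = ""

    def __str__(self) -> str:  # "3732-3764 (exon 16)"
        s = f"{self.start}-{self.end}"
        return f"{s} ({self.exon_label})" if self.exon_label else s

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _merge_exon_labels(first: str, second: str) -> str:
    """'exon 1' + 'exon 2' -> 'exon 1-2'; degenerate cases fall through."""
    a = first.removeprefix("exon ").strip()
    b = second.removeprefix("exon ").strip()
    if not a:
        return second
    if not b or a == b:
        return first
    return f"exon {a.split('-')[0]}-{b.split('-')[-1]}"


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    category: str
    acceptor_span: Span
    donor_span: Span | None = None
    mismatches: int = 0
    adapter_clipped: int = 0
    trailing_trimmed: int = 0

    def span_columns(self) -> tuple[str, str]:
        """(donor column, acceptor column) the way junction-region read
        tables are conventionally printed: wild-type reads get one merged
        acceptor-gene span, fusion reads get separate donor and acceptor
        spans."""
        if self.category == "FUSION" and self.donor_span is not None:
            return str(self.donor_span), str(self.acceptor_span)
        if self.category == "WILDTYPE" and self.donor_span is not None:
            merged = Span(
                self.acceptor_span.accession,
                self.donor_span.start,
                self.acceptor_span.end,
                _merge_exon_labels(self.donor_span.exon_label, self.acceptor_span.exon_label),
            )
            return "", str(merged)
        return "", str(self.acceptor_span)


@dataclass
class JunctionCall:
    donor_accession: str
    donor_gene: str
    donor_breakpoint: int
    donor_exon: str
    acceptor_accession: str
    acceptor_gene: str
    acceptor_start: int
    acceptor_exon: str
    supporting_reads: int
    frame: str = "unknown"  # 'in_frame' | 'out_of_frame' | 'unknown'
    donor_codon: int | None = None
    acceptor_codon: int | None = None

    def as_dict(self) -> dict:
        return {
            "donor": {
                "accession": self.donor_accession,
                "gene": self.donor_gene,
                "breakpoint": self.donor_breakpoint,
                "exon": self.donor_exon,
            },
            "acceptor": {
                "accession": self.acceptor_accession,
                "gene": self.acceptor_gene,
                "start": self.acceptor_start,
                "exon": self.acceptor_exon,
            },
            "supporting_reads": self.supporting_reads,
            "frame": self.frame,
            "donor_codon": self.donor_codon,
            "acceptor_codon": self.acceptor_codon,
        }


def _hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N always mismatches."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def match_flank_suffix(
    flank: str,
    ref: TranscriptReference,
    params: ClassifierParams,
) -> tuple[int, int] | None:
    """Best placement of ``flank`` as a suffix ending somewhere in ``ref``.

    Returns ``(end_coordinate, mismatches)`` minimising mismatches (ties:
    largest end coordinate), or None when no placement fits the mismatch
    budget or the flank does not fit inside the stored window.
    """
    if not flank:
        raise ValueError("empty flank")
    flank = flank.upper()
    w0, w1 = ref.window
    n = len(flank)
    if n > w1 - w0 + 1:
        return None
    budget = ceil_mismatch_budget(params.max_mismatch_rate, n)
    best: tuple[int, int] | None = None
    for end in range(w0 + n - 1, w1 + 1):
        mm = _hamming(flank, ref.sequence[end - n + 1 - w0 : end + 1 - w0])
        if mm > budget:
            continue
        if best is None or mm < best[1] or (mm == best[1] and end > best[0]):
            best = (end, mm)
    return best


@dataclass(frozen=True)
class PrefixMatch:
    """Result of extending a downstream flank along the acceptor."""

    end: int  # last matched mRNA coordinate (start-1 when nothing matched)
    mismatches: int
    adapter_clipped: int
    trailing_trimmed: int


def _adapter_clip_points(flank: str, params: ClassifierParams) -> list[int]:
    """All indices i such that flank[i:] is explained by the adapter: the
    adapter (or a >=min_overlap prefix of it, when the flank ends first)
    starting exactly at i.  Bases after a complete adapter are read-through
    noise and clip with it."""
    points = []
    adapter = params.adapter
    for i in range(len(flank)):
        m = min(len(adapter), len(flank) - i)
        if m >= params.adapter_min_overlap and flank[i : i + m] == adapter[:m]:
            points.append(i)
    return points


def match_flank_prefix(
    flank: str,
    ref: TranscriptReference,
    start: int,
    params: ClassifierParams,
) -> PrefixMatch:
    """Extend ``flank`` along ``ref`` from coordinate ``start``.

    Candidate explanations are enumerated: clip the flank at each position
    where the adapter can begin (3' read-through), or not at all; extend the
    remainder base-by-base counting mismatches; trim the maximal trailing
    run of contiguous mismatches (terminal sequencing errors); drop
    candidates whose surviving mismatches exceed the budget.  The winner has
    the fewest mismatches, then the longest extension, then the largest
    adapter clip (the more specific explanation of the tail).

    The degenerate candidate that trims everything always qualifies, so a
    result is always returned; ``end == start - 1`` means nothing matched.
    """
    if not ref.contains(start) and flank:
        raise ValueError(f"start {start} outside {ref.accession} window {ref.window}")
    flank = flank.upper()
    w0, w1 = ref.window
    candidates: list[PrefixMatch] = []
    for clip_at in _adapter_clip_points(flank, params) + [len(flank)]:
        kept = flank[:clip_at]
        clipped = len(flank) - clip_at
        room = w1 - start + 1
        extendable = min(len(kept), room)
        overflow = len(kept) - extendable  # bases past the stored window
        flags = [
            kept[i] == ref.sequence[start + i - w0] and kept[i] != "N"
            for i in range(extendable)
        ]
        # trim the trailing mismatch run; if the interior still violates the
        # budget, keep backing off to the longest match-ending prefix that
        # satisfies it (matched_len = 0 always does)
        mm_prefix = [0]
        for ok in flags:
            mm_prefix.append(mm_prefix[-1] + (not ok))
        matched_len = extendable
        while matched_len > 0 and (
            not flags[matched_len - 1]
            or mm_prefix[matched_len]
            > ceil_mismatch_budget(params.max_mismatch_rate, matched_len)
        ):
            matched_len -= 1
        mm = mm_prefix[matched_len]
        trailing = (extendable - matched_len) + overflow
        candidates.append(PrefixMatch(start + matched_len - 1, mm, clipped, trailing))
    return min(candidates, key=lambda c: (c.mismatches, -c.end, -c.adapter_clipped))


def classify_read(
    ar: AnchoredRead,
    donor_refs: Sequence[TranscriptReference],
    acceptor_ref: TranscriptReference,
    spec: AnchorSpec,
    params: ClassifierParams | None = None,
) -> ClassifiedRead:
    """Assign a retrieved read to FUSION / WILDTYPE / OTHER (or
    UNINFORMATIVE / AMBIGUOUS) and report its reference spans."""
    params = params or ClassifierParams()
    seq = ar.oriented_sequence.upper()
    off = ar.anchor_offset
    if seq[off : off + len(spec.anchor)] != spec.anchor:
        raise ValueError(f"{ar.read.read_id}: anchor not at recorded offset (corrupt input)")

    upstream = seq[:off]
    downstream = seq[off + len(spec.anchor) :]

    # downstream of the anchor is acceptor sequence for every category
    if downstream:
        pm = match_flank_prefix(downstream, acceptor_ref, spec.acceptor_end + 1, params)
    else:
        pm = PrefixMatch(spec.acceptor_end, 0, 0, 0)
    acc_span = Span(
        acceptor_ref.accession,
        spec.acceptor_start,
        max(pm.end, spec.acceptor_end),
        acceptor_ref.exon_label_for(spec.acceptor_start, max(pm.end, spec.acceptor_end)),
    )

    def done(category: str, donor_span: Span | None, upstream_mm: int) -> ClassifiedRead:
        return ClassifiedRead(
            read_id=ar.read.read_id,
            category=category,
            acceptor_span=acc_span,
            donor_span=donor_span,
            mismatches=upstream_mm + pm.mismatches,
            adapter_clipped=pm.adapter_clipped,
            trailing_trimmed=pm.trailing_trimmed,
        )

    if len(upstream) < params.min_upstream_flank:
        return done("UNINFORMATIVE", None, 0)

    # wild-type hypothesis: upstream continues the acceptor transcript and
    # must end at the base immediately before the anchor
    wt_mm: int | None = None
    wt_end = spec.acceptor_start - 1
    w0, _ = acceptor_ref.window
    if wt_end - len(upstream) + 1 >= w0 and acceptor_ref.contains(wt_end):
        mm = _hamming(upstream, subseq(acceptor_ref, wt_end - len(upstream) + 1, wt_end))
        if mm <= ceil_mismatch_budget(params.max_mismatch_rate, len(upstream)):
            wt_mm = mm

    # fusion hypothesis: upstream is a suffix of some donor mRNA
    fusion_best: tuple[int, int, TranscriptReference] | None = None
    for donor in donor_refs:
        if donor.accession == acceptor_ref.accession:
            continue
        hit = match_flank_suffix(upstream, donor, params)
        if hit is None:
            continue
        end, mm = hit
        if fusion_best is None or mm < fusion_best[1]:
            fusion_best = (end, mm, donor)

    if wt_mm is None and fusion_best is None:
        return done("OTHER", None, 0)
    if fusion_best is None or (wt_mm is not None and wt_mm < fusion_best[1]):
        assert wt_mm is not None
        span = Span(
            acceptor_ref.accession,
            wt_end - len(upstream) + 1,
            wt_end,
            acceptor_ref.exon_label_for(wt_end - len(upstream) + 1, wt_end),
        )
        return done("WILDTYPE", span, wt_mm)
    if wt_mm is not None and wt_mm == fusion_best[1]:
        if params.tie_break == "prefer_wildtype":
            span = Span(
                acceptor_ref.accession,
                wt_end - len(upstream) + 1,
                wt_end,
                acceptor_ref.exon_label_for(wt_end - len(upstream) + 1, wt_end),
            )
            return done("WILDTYPE", span, wt_mm)
        return done("AMBIGUOUS", None, wt_mm)
    end, mm, donor = fusion_best
    span = Span(
        donor.accession,
        end - len(upstream) + 1,
        end,
        donor.exon_label_for(end - len(upstream) + 1, end),
    )
    return done("FUSION", span, mm)


def call_junction(
    classified: Iterable[ClassifiedRead],
    donor_refs: Sequence[TranscriptReference] = (),
    acceptor_ref: TranscriptReference | None = None,
) -> list[JunctionCall]:
    """Aggregate FUSION reads into junction calls.

    Reads are grouped by (donor accession, donor breakpoint); calls are
    ordered by decreasing support, then accession, then coordinate.
    """
    genes = {r.accession: r.gene_symbol for r in donor_refs}
    if acceptor_ref is not None:
        genes[acceptor_ref.accession] = acceptor_ref.gene_symbol
    groups: dict[tuple[str, int], list[ClassifiedRead]] = {}
    for cr in classified:
        if cr.category != "FUSION" or cr.donor_span is None:
            continue
        groups.setdefault((cr.donor_span.accession, cr.donor_span.end), []).append(cr)

    calls = []
    for (acc, bp), members in groups.items():
        first = members[0]
        calls.append(
            JunctionCall(
                donor_accession=acc,
                donor_gene=genes.get(acc, ""),
                donor_breakpoint=bp,
                donor_exon=first.donor_span.exon_label,  # type: ignore[union-attr]
                acceptor_accession=first.acceptor_span.accession,
                acceptor_gene=genes.get(first.acceptor_span.accession, ""),
                acceptor_start=first.acceptor_span.start,
                acceptor_exon=first.acceptor_span.exon_label,
                supporting_reads=len(members),
            )
        )
    calls.sort(key=lambda c: (-c.supporting_reads, c.donor_accession, c.donor_breakpoint))
    return calls


def frame_check(
    call: JunctionCall,
    donor_ref: TranscriptReference,
    acceptor_ref: TranscriptReference,
) -> JunctionCall:
    """Determine whether the fused transcript preserves the reading frame.

    With donor CDS length up to the breakpoint L_d = breakpoint - cds_start_d
    + 1 and acceptor CDS bases skipped L_a = acceptor_start - cds_start_a,
    the downstream acceptor codons stay intact iff L_d == L_a (mod 3).  The
    junction codons are donor_codon = ceil(L_d / 3) and acceptor_codon =
    floor(L_a / 3) + 1 (the codon the acceptor resumes in).
    """
    if donor_ref.cds_start is None or acceptor_ref.cds_start is None:
        call.frame = "unknown"
        return call
    ld = call.donor_breakpoint - donor_ref.cds_start + 1
    la = call.acceptor_start - acceptor_ref.cds_start
    if ld < 1 or la < 0:
        call.frame = "unknown"
        return call
    call.frame = "in_frame" if ld % 3 == la % 3 else "out_of_frame"
    call.donor_codon = -(-ld // 3)
    call.acceptor_codon = la // 3 + 1
    return call


def write_classified_tsv(classified: Iterable[ClassifiedRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "read_id\tcategory\tdonor_span\tacceptor_span\tmismatches\t"
            "adapter_clipped\ttrailing_trimmed\n"
        )
        for cr in classified:
            donor_col, acc_col = cr.span_columns()
            fh.write(
                f"{cr.read_id}\t{cr.category}\t{donor_col}\t{acc_col}\t"
                f"{cr.mismatches}\t{cr.adapter_clipped}\t{cr.trailing_trimmed}\n"
            )
            n += 1
    return n


def write_junction_json(calls: Sequence[JunctionCall], path: str | Path, **extra) -> None:
    payload: dict = {"junction_calls": [c.as_dict() for c in calls]}
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
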