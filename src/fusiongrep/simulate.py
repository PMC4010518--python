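"""Synthetic single-end RNA-seq library with a ground-truth ledger.

The generator emulates the kind of library the anchor-grep procedure was
designed for: 101-nt single-end reads drawn from wild-type transcript
templates plus a fusion transcript present at very low abundance, with
i.i.d. substitution errors and Illumina 3'-adapter read-through whenever
the cDNA insert is shorter than the read.  Every emitted read is logged in
a truth ledger so retrieval sensitivity, classification specificity and
junction-coordinate accuracy can be measured exactly.

Fragment lengths are drawn from a truncated normal; reads are always taken
from the 5' end of the fragment in template sense (single-end, sense-strand
model — the retrieval step's reverse-complement option is exercised with
hand-built reads in the tests instead).  Substitutions never land in
adapter fill.  Given the same seed and config the FASTQ bytes are identical
across runs (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import ClassifiedRead, ClassifierParams, JunctionCall
from .retrieval import AnchorSpec

# TruSeq adapter stem plus downstream adapter sequence, as it appears in
# 3'-read-through tails of real 101-nt libraries
DEFAULT_READTHROUGH = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SimSource",
    "SimulationConfig",
    "SimReadTruth",
    "simulate_library",
    "evaluate_detection",
    "write_fastq",
    "write_truth_tsv",
    "DetectionMetrics",
    "DEFAULT_READTHROUGH",
]


@dataclass(frozen=True)
class SimSource:
    """One template transcript reads can originate from.

    ``junction`` is the 0-based index of the last donor base for a fusion
    template, None for a wild-type template.
    """

    label: str
    sequence: str
    weight: float = 1.0
    junction: int | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"source {self.label}: negative weight")
        if self.junction is not None and not 0 <= self.junction < len(self.sequence) - 1:
            raise ValueError(f"source {self.label}: junction outside template")


@dataclass(frozen=True)
class SimulationConfig:
    """Library-generation parameters.

    Defaults describe a desk-scale version of a deep 101-nt Illumina RNA-seq
    library: per-base substitution rate 0.005, fragment lengths ~N(150, 30)
    truncated, junction reads at a rare fixed fraction of the library.
    """

    seed: int
    sources: tuple[SimSource, ...]
    n_reads: int = 100_000
    read_length: int = 101
    substitution_rate: float = 0.005
    insert_mean: float = 150.0
    insert_sd: float = 30.0
    insert_min: int = 30
    adapter: str = DEFAULT_READTHROUGH
    fusion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("at least one source is required")
        if not 0 <= self.fusion_fraction <= 1:
            raise ValueError("fusion_fraction must be in [0, 1]")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        wt = [s for s in self.sources if s.junction is None]
        fus = [s for s in self.sources if s.junction is not None]
        if self.fusion_fraction > 0 and not fus:
            raise ValueError("fusion_fraction > 0 but no fusion source present")
        if self.fusion_fraction < 1 and not wt:
            raise ValueError("fusion_fraction < 1 but no wild-type source present")
        if sum(s.weight for s in wt) == 0 and wt and self.fusion_fraction < 1:
            raise ValueError("wild-type source weights sum to zero")


@dataclass(frozen=True)
class SimReadTruth:
    source_label: str
    template_start: int
    covers_junction: bool
    junction_overhang_5p: int  # donor (pre-junction) bases inside the read
    n_errors_injected: int
    adapter_bases: int


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str


def _pick_sources(cfg: SimulationConfig, rng: np.random.Generator) -> list[SimSource]:
    wt = [s for s in cfg.sources if s.junction is None]
    fus = [s for s in cfg.sources if s.junction is not None]
    out = []
    is_fusion = rng.random(cfg.n_reads) < cfg.fusion_fraction
    wt_w = np.array([s.weight for s in wt], dtype=float)
    wt_p = wt_w / wt_w.sum() if wt and wt_w.sum() > 0 else None
    fus_w = np.array([s.weight for s in fus], dtype=float)
    fus_p = fus_w / fus_w.sum() if fus and fus_w.sum() > 0 else None
    for flag in is_fusion:
        if flag:
            out.append(fus[rng.choice(len(fus), p=fus_p)] if len(fus) > 1 else fus[0])
        else:
            out.append(wt[rng.choice(len(wt), p=wt_p)] if len(wt) > 1 else wt[0])
    return out


def simulate_library(cfg: SimulationConfig) -> tuple[list[SimulatedRead], dict[str, SimReadTruth]]:
    """Generate the library and its truth ledger (one entry per read)."""
    rng = np.random.default_rng(cfg.seed)
    picks = _pick_sources(cfg, rng)
    reads: list[SimulatedRead] = []
    truth: dict[str, SimReadTruth] = {}
    for i, src in enumerate(picks):
        template = src.sequence
        tlen = len(template)
        if tlen < cfg.insert_min:
            raise RuntimeError(
                f"source {src.label}: template length {tlen} below insert_min "
                f"{cfg.insert_min}"
            )
        # truncated normal: a fragment cannot exceed its template, and
        # fragmenting a short transcript yields the whole transcript
        cand = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = min(max(cand, cfg.insert_min), tlen)
        start = int(rng.integers(0, tlen - insert + 1))
        copied = min(insert, cfg.read_length)
        fragment = template[start : start + copied]
        adapter_fill = 0
        if copied < cfg.read_length:
            need = cfg.read_length - copied
            fill = (cfg.adapter * (need // len(cfg.adapter) + 1))[:need]
            adapter_fill = need
        else:
            fill = ""
        # substitutions only in template-derived bases
        arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
        err_pos = np.nonzero(rng.random(copied) < cfg.substitution_rate)[0]
        for p in err_pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
        seq = arr.tobytes().decode() + fill
        rid = f"sim{i:07d}"
        reads.append(SimulatedRead(rid, seq))
        end = start + copied - 1  # last template position in the read
        covers = src.junction is not None and start <= src.junction and end >= src.junction + 1
        overhang = (src.junction - start + 1) if covers else 0
        truth[rid] = SimReadTruth(src.label, start, covers, overhang, len(err_pos), adapter_fill)
    return reads, truth


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path, quality_char: str = "I") -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")
            n += 1
    return n


def write_truth_tsv(truth: Mapping[str, SimReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsource\ttemplate_start\tcovers_junction\t"
            "junction_overhang_5p\tn_errors\tadapter_bases\n"
        )
        for rid, t in truth.items():
            fh.write(
                f"{rid}\t{t.source_label}\t{t.template_start}\t{int(t.covers_junction)}\t"
                f"{t.junction_overhang_5p}\t{t.n_errors_injected}\t{t.adapter_bases}\n"
            )


@dataclass(frozen=True)
class DetectionMetrics:
    n_anchor_covered: int          # reads whose clean fragment contains the anchor
    n_retrieved: int               # of those, how many the exact search found
    retrieval_sensitivity: float
    n_eligible_junction_reads: int  # junction reads with full anchor + enough donor flank
    n_fusion_detected: int          # of those, classified FUSION
    classification_sensitivity: float
    false_positive_fusions: int     # FUSION-classified reads from non-fusion sources
    junction_calls_total: int
    junction_calls_correct: int
    junction_accuracy: float


def evaluate_detection(
    truth: Mapping[str, SimReadTruth],
    retrieved_ids: Iterable[str],
    classified: Sequence[ClassifiedRead],
    calls: Sequence[JunctionCall],
    cfg: SimulationConfig,
    spec: AnchorSpec,
    params: ClassifierParams,
    planted: tuple[int, int],
) -> DetectionMetrics:
    """Score retrieval/classification/calling against the truth ledger.

    ``planted`` is the (donor breakpoint, acceptor start) used to build the
    fusion template, in mRNA coordinates.
    """
    retrieved = set(retrieved_ids)
    unknown = retrieved - set(truth)
    if unknown:
        raise ValueError(f"{len(unknown)} retrieved read ids absent from the truth ledger")
    class_by_id = {}
    for cr in classified:
        if cr.read_id not in truth:
            raise ValueError(f"classified read {cr.read_id} absent from the truth ledger")
        class_by_id[cr.read_id] = cr

    templates = {s.label: s for s in cfg.sources}
    n_cov = n_ret = 0
    n_elig = n_det = 0
    fp = 0
    anchor = spec.anchor
    for rid, t in truth.items():
        src = templates[t.source_label]
        copied = cfg.read_length - t.adapter_bases  # template-derived bases
        clean = src.sequence[t.template_start : t.template_start + copied]
        if anchor in clean:
            n_cov += 1
            if rid in retrieved:
                n_ret += 1
        cr = class_by_id.get(rid)
        if src.junction is None:
            if cr is not None and cr.category == "FUSION":
                fp += 1
            continue
        end = t.template_start + copied - 1
        full_anchor = t.covers_junction and end - src.junction >= len(anchor)
        if full_anchor and t.junction_overhang_5p >= params.min_upstream_flank:
            n_elig += 1
            if cr is not None and cr.category == "FUSION":
                n_det += 1
    correct = sum(
        1 for c in calls if (c.donor_breakpoint, c.acceptor_start) == planted
    )
    return DetectionMetrics(
        n_anchor_covered=n_cov,
        n_retrieved=n_ret,
        retrieval_sensitivity=n_ret / n_cov if n_cov else float("nan"),
        n_eligible_junction_reads=n_elig,
        n_fusion_detected=n_det,
        classification_sensitivity=n_det / n_elig if n_elig else float("nan"),
        false_positive_fusions=fp,
        junction_calls_total=len(calls),
        junction_calls_correct=correct,
        junction_accuracy=correct / len(calls) if calls else float("nan"),
    )
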