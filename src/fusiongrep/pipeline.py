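"""End-to-end orchestration: retrieve -> classify -> call -> report.

The pipeline automates the manual procedure of grepping a read file for the
acceptor anchor, classifying every hit against the partner references, and
aggregating junction calls, writing per-stage artifacts and a JSON report.

Config is a flat YAML mapping::

    reads: reads.fastq            # FASTQ/FASTA, optionally .gz
    reads2: mate2.fastq           # optional second file, scanned independently
    reference_fasta: refs.fasta
    reference_annotation: refs.tsv
    acceptor: NM_004380.2         # which reference is the acceptor
    anchor: ATTTTGGATCATTGTTTGAC  # optional, with acceptor_start
    acceptor_start: 290
    search_revcomp: false
    out_dir: results/
    params:                       # optional ClassifierParams overrides
      max_mismatch_rate: 0.10
      adapter: AGATCGGAAGAGC
      adapter_min_overlap: 5
      min_upstream_flank: 6
      tie_break: prefer_wildtype
"""

from __future__ import annotations

import datetime
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass
from itertools import chain
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .classify import (
    ClassifierParams,
    JunctionCall,
    call_junction,
    classify_read,
    frame_check,
    write_classified_tsv,
    write_junction_json,
)
from .references import load_reference
from .retrieval import AnchorSpec, read_sequences, scan_reads, write_anchored_tsv

logger = logging.getLogger("fusiongrep")

REPORT_SCHEMA_VERSION = 1

__all__ = ["PipelineReport", "run_pipeline", "load_config"]


@dataclass
class PipelineReport:
    n_input_reads: int
    n_anchored: int
    category_counts: dict[str, int]
    junction_calls: list[JunctionCall]
    parameters: dict
    version: str
    started: str
    finished: str

    def as_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_input_reads": self.n_input_reads,
            "n_anchored": self.n_anchored,
            "category_counts": self.category_counts,
            "junction_calls": [c.as_dict() for c in self.junction_calls],
            "parameters": self.parameters,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
        }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _validate(cfg: Mapping) -> None:
    for key in ("reads", "reference_fasta", "reference_annotation", "acceptor", "out_dir"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    for key in ("reads", "reads2", "reference_fasta", "reference_annotation"):
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"config {key}: no such file {cfg[key]}")


def run_pipeline(config: str | Path | Mapping) -> PipelineReport:
    """Run all stages; deterministic for fixed inputs and config."""
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    _validate(cfg)

    refs = load_reference(cfg["reference_fasta"], cfg["reference_annotation"])
    acceptor_acc = cfg["acceptor"]
    if acceptor_acc not in refs:
        raise ValueError(f"acceptor {acceptor_acc} not among loaded references {sorted(refs)}")
    acceptor = refs[acceptor_acc]
    donors = [r for acc, r in sorted(refs.items()) if acc != acceptor_acc]

    spec_kwargs = {}
    if cfg.get("anchor"):
        spec_kwargs["anchor"] = str(cfg["anchor"]).upper()
    if cfg.get("acceptor_start"):
        spec_kwargs["acceptor_start"] = int(cfg["acceptor_start"])
    spec = AnchorSpec(
        acceptor_accession=acceptor_acc,
        search_revcomp=bool(cfg.get("search_revcomp", False)),
        **spec_kwargs,
    )
    params = ClassifierParams(**(cfg.get("params") or {}))

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    streams = [read_sequences(cfg["reads"])]
    if cfg.get("reads2"):
        streams.append(read_sequences(cfg["reads2"]))

    n_input = 0
    anchored = []

    def counting(stream):
        nonlocal n_input
        for read in stream:
            n_input += 1
            yield read

    for ar in scan_reads(counting(chain(*streams)), spec):
        anchored.append(ar)
    logger.info("retrieval: %d/%d reads contain the anchor", len(anchored), n_input)
    write_anchored_tsv(anchored, out_dir / "anchored_reads.tsv")

    classified = [classify_read(ar, donors, acceptor, spec, params) for ar in anchored]
    counts = Counter(cr.category for cr in classified)
    logger.info("classification: %s", dict(counts))
    write_classified_tsv(classified, out_dir / "classified_reads.tsv")

    calls = call_junction(classified, donors, acceptor)
    by_acc = {r.accession: r for r in donors}
    calls = [
        frame_check(c, by_acc[c.donor_accession], acceptor) if c.donor_accession in by_acc else c
        for c in calls
    ]

    finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    report = PipelineReport(
        n_input_reads=n_input,
        n_anchored=len(anchored),
        category_counts={cat: counts.get(cat, 0) for cat in ("FUSION", "WILDTYPE", "OTHER", "UNINFORMATIVE", "AMBIGUOUS")},
        junction_calls=calls,
        parameters={"anchor_spec": asdict(spec), "classifier": asdict(params)},
        version=__version__,
        started=started,
        finished=finished,
    )
    write_junction_json(calls, out_dir / "junctions.json")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
        fh.write("\n")
    return report
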