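"""Auditing fusion-caller output against karyotype breakpoints.

Genome-wide fusion callers emit long candidate lists (hundreds of entries);
when a karyotype is available, the biologically plausible candidates are the
ones whose partner genes map to the rearranged cytobands.  This module
parses generic caller tables, checks whether a specific target pair was
called at all (under symbol aliases such as KAT6A = MYST3 = MOZ,
CREBBP = CBP), filters candidates by cytoband, and renders the ISCN
translocation string a candidate pair would imply.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .references import GeneLocus

__all__ = [
    "FusionCallRecord",
    "parse_caller_table",
    "load_gene_loci",
    "audit_target_pair",
    "cytoband_filter",
    "iscn_translocation",
]


@dataclass(frozen=True)
class FusionCallRecord:
    gene5: str
    gene3: str
    rank: int
    score: float | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("gene symbols must be non-empty")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def parse_caller_table(path: str | Path, column_map: Mapping[str, str]) -> list[FusionCallRecord]:
    """Read a caller TSV/CSV into records.

    ``column_map`` maps logical names to actual column names.  Either
    ``pair`` (one "GENE1-GENE2" column, split on the last hyphen) or
    ``gene5``/``gene3`` must be mapped; ``rank`` and ``score`` are optional
    (rank defaults to row order).  Unmapped columns are preserved in
    ``extra``.
    """
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for logical, actual in column_map.items():
            if actual not in header:
                raise ValueError(f"{path}: mapped column {actual!r} (for {logical!r}) not in header")
        mapped_cols = set(column_map.values())
        for i, row in enumerate(reader, start=1):
            if "pair" in column_map:
                pair = row[column_map["pair"]]
                gene5, sep, gene3 = pair.rpartition("-")
                if not sep:
                    raise ValueError(f"{path} row {i}: cannot split pair {pair!r}")
            else:
                gene5 = row[column_map["gene5"]]
                gene3 = row[column_map["gene3"]]
            rank = int(row[column_map["rank"]]) if "rank" in column_map else i
            score = None
            if "score" in column_map and row[column_map["score"]] not in (None, ""):
                score = float(row[column_map["score"]])
            extra = {k: v for k, v in row.items() if k not in mapped_cols}
            records.append(FusionCallRecord(gene5.strip(), gene3.strip(), rank, score, extra))
    ranks = [r.rank for r in records]
    if len(set(ranks)) != len(ranks):
        dupes = sorted({r for r in ranks if ranks.count(r) > 1})
        raise ValueError(f"{path}: duplicate ranks {dupes}")
    return records


def load_gene_loci(path: str | Path) -> dict[str, GeneLocus]:
    """Gene -> cytoband TSV (columns: gene, cytoband)."""
    loci = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            locus = GeneLocus(row["gene"].strip(), row["cytoband"].strip())
            locus.parse_band()  # validate eagerly
            loci[locus.gene_symbol] = locus
    return loci


def _canon(symbol: str, aliases: Mapping[str, str]) -> str:
    symbol = symbol.strip().upper()
    return aliases.get(symbol, symbol).upper()


def audit_target_pair(
    records: Iterable[FusionCallRecord],
    gene_a: str,
    gene_b: str,
    aliases: Mapping[str, str] | None = None,
) -> tuple[bool, int | None]:
    """Is the (orientation-insensitive) gene pair in the caller output, and
    at what best rank?  ``aliases`` translates synonyms to canonical symbols
    (e.g. {"MYST3": "KAT6A", "CBP": "CREBBP"})."""
    aliases = aliases or {}
    target = frozenset((_canon(gene_a, aliases), _canon(gene_b, aliases)))
    best: int | None = None
    for rec in records:
        pair = frozenset((_canon(rec.gene5, aliases), _canon(rec.gene3, aliases)))
        if pair == target and (best is None or rec.rank < best):
            best = rec.rank
    return best is not None, best


def cytoband_filter(
    records: Iterable[FusionCallRecord],
    loci: Mapping[str, GeneLocus],
    bands: Iterable[str],
    mode: str = "any",
    aliases: Mapping[str, str] | None = None,
) -> tuple[list[FusionCallRecord], int]:
    """Keep records whose partner genes lie in the karyotype breakpoint
    bands: mode='any' needs one partner in the band set, mode='both' needs
    both.  Returns (kept records, number dropped as unresolvable).

    Band matching is prefix-aware at sub-band resolution: a gene annotated
    16p13.3 matches the band 16p13.
    """
    if mode not in ("any", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    aliases = aliases or {}
    bandset = {b.strip() for b in bands}
    canon_loci = {k.upper(): v for k, v in loci.items()}

    def band_of(gene: str) -> str | None:
        locus = canon_loci.get(_canon(gene, aliases))
        return locus.cytoband if locus else None

    def in_bands(cytoband: str) -> bool:
        return any(cytoband == b or cytoband.startswith(b + ".") or b.startswith(cytoband + ".")
                   for b in bandset)

    kept, dropped = [], 0
    for rec in records:
        b5, b3 = band_of(rec.gene5), band_of(rec.gene3)
        if b5 is None or b3 is None:
            dropped += 1
            continue
        flags = (in_bands(b5), in_bands(b3))
        if (mode == "any" and any(flags)) or (mode == "both" and all(flags)):
            kept.append(rec)
    return kept, dropped


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}


def iscn_translocation(locus_a: GeneLocus, locus_b: GeneLocus) -> str:
    """ISCN string for the reciprocal translocation implied by a fusion of
    two genes, e.g. (MYST3 at 8p11, DTX3L at 3q21) -> "t(3;8)(q21;p11)".

    Chromosomes are ordered 1..22, X, Y; bands follow their chromosomes.
    Intrachromosomal rearrangements are not expressible as t().
    """
    ca, arma, banda = locus_a.parse_band()
    cb, armb, bandb = locus_b.parse_band()
    if ca == cb:
        raise ValueError(
            f"{locus_a.gene_symbol} and {locus_b.gene_symbol} are both on chromosome "
            f"{ca}: intrachromosomal rearrangement not expressible as t()"
        )
    first = (_CHROM_ORDER[ca], ca, arma + banda)
    second = (_CHROM_ORDER[cb], cb, armb + bandb)
    if first[0] > second[0]:
        first, second = second, first
    return f"t({first[1]};{second[1]})({first[2]};{second[2]})"
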