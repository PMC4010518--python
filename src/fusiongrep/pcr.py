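"""In-silico RT-PCR on (possibly chimeric) transcript templates.

Used to replicate the verification step: build the fusion mRNA, place the
published primer pair on it, and check the amplicon size (352 bp for the
type-1 KAT6A-CREBBP junction with MOZ-3558F / CBP-431R on the full mRNA
references).

The reverse primer is given 5'->3' on the antisense strand, as primers are
conventionally written, so it binds where its reverse complement occurs in
the template.  No thermodynamics: binding is exact (optionally
mismatch-tolerant) string matching.
"""

from __future__ import annotations

from dataclasses import dataclass

from .references import VALID_BASES
from .retrieval import revcomp

# the published primer pair for the type-1 junction
MOZ_3558F = "GAGGCCAATGCCAAGATTAGAAC"
CBP_431R = "GTTGATACTAGAGCCGCTGCCTC"

__all__ = ["PrimerPair", "PrimerSite", "find_primer_sites", "amplicon", "MOZ_3558F", "CBP_431R"]


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    name_fwd: str = "fwd"
    name_rev: str = "rev"

    def __post_init__(self) -> None:
        for name, seq in ((self.name_fwd, self.fwd), (self.name_rev, self.rev)):
            if len(seq) < 15:
                raise ValueError(f"primer {name} shorter than 15 nt")
            bad = set(seq.upper()) - (VALID_BASES - {"N"})
            if bad:
                raise ValueError(f"primer {name} contains non-ACGT characters {sorted(bad)}")


@dataclass(frozen=True)
class PrimerSite:
    """0-based positions of a productive primer placement on the template."""

    fwd_pos: int
    rev_pos: int  # start of the reverse-complemented reverse-primer site
    rev_end: int  # inclusive end of that site

    @property
    def product_length(self) -> int:
        return self.rev_end - self.fwd_pos + 1


def _find_all(template: str, probe: str, max_mismatch: int) -> list[int]:
    hits = []
    n = len(probe)
    if max_mismatch == 0:
        i = template.find(probe)
        while i >= 0:
            hits.append(i)
            i = template.find(probe, i + 1)
        return hits
    for i in range(len(template) - n + 1):
        mm = sum(1 for a, b in zip(template[i : i + n], probe) if a != b)
        if mm <= max_mismatch:
            hits.append(i)
    return hits


def find_primer_sites(template: str, primers: PrimerPair, max_mismatch: int = 0) -> list[PrimerSite]:
    """All productive (forward, reverse) placements on the sense template."""
    if not template:
        raise ValueError("empty template")
    template = template.upper()
    fwd = primers.fwd.upper()
    rev_rc = revcomp(primers.rev.upper())
    sites = []
    for f in _find_all(template, fwd, max_mismatch):
        for r in _find_all(template, rev_rc, max_mismatch):
            rev_end = r + len(rev_rc) - 1
            if f < rev_end:
                sites.append(PrimerSite(f, r, rev_end))
    return sites


def amplicon(template: str, primers: PrimerPair, max_mismatch: int = 0) -> tuple[int, str]:
    """(length, sequence) of the unique PCR product.

    Errors out when zero or multiple productive primer placements exist,
    listing the candidates — a multi-product PCR is not a verification.
    """
    sites = find_primer_sites(template, primers, max_mismatch)
    if len(sites) != 1:
        detail = ", ".join(f"{s.fwd_pos}..{s.rev_end}" for s in sites) or "none"
        raise ValueError(f"expected exactly one primer-site pair, found {len(sites)} ({detail})")
    site = sites[0]
    product = template.upper()[site.fwd_pos : site.rev_end + 1]
    return len(product), product
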