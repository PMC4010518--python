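"""In-silico RT-PCR across a fusion junction.

The wet-lab verification of a called junction is an RT-PCR with one primer
per partner gene; the product size is predicted by the junction coordinates.
On the full NM_006766.3/NM_004380.2 references (user-supplied; see
fusiongrep.data.load_full_references) the published primer pair
MOZ-3558F/CBP-431R yields a 352 bp product.  This example demonstrates the
machinery on the packaged fixture windows with a primer pair chosen inside
them, where the product size follows from the same arithmetic.
"""

from fusiongrep import PrimerPair, amplicon, build_fusion_transcript, find_primer_sites, subseq
from fusiongrep.data import load_fixture_references
from fusiongrep.retrieval import revcomp

kat6a, crebbp = load_fixture_references()
fusion = build_fusion_transcript(kat6a, 3764, crebbp, 290)
print(f"type-1 fusion template from fixtures: {len(fusion)} nt "
      f"(KAT6A 3686-3764 + CREBBP 290-380)")

# primers inside the fixture windows: forward on KAT6A, reverse on CREBBP
fwd = subseq(kat6a, 3700, 3721)          # 22-mer ending 43 nt before the junction
rev = revcomp(subseq(crebbp, 340, 362))  # written 5'->3' on the antisense strand
primers = PrimerPair(fwd, rev, "KAT6A-3700F", "CREBBP-362R")

(site,) = find_primer_sites(fusion, primers)
length, product = amplicon(fusion, primers)
print(f"forward site at template position {site.fwd_pos}, "
      f"reverse site ends at {site.rev_end}")
print(f"amplicon: {length} bp")
expected = (3764 - 3700 + 1) + (362 - 290 + 1)
print(f"expected from junction arithmetic: (3764-3700+1) + (362-290+1) = {expected}")
print(
    "meaning: a product of exactly this size on patient cDNA, and no product\n"
    "without the junction, confirms the called breakpoint coordinates."
)
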