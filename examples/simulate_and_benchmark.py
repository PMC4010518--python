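"""Simulate a low-abundance fusion library and measure detection.

Generates 50,000 101-nt reads (wild-type CREBBP and KAT6A background plus
junction-spanning fusion reads at 2e-4 abundance, substitution rate 0.005,
3'-adapter read-through on short inserts), runs the full
retrieve-classify-call chain, and scores it against the simulator's truth
ledger.  The headline number: exact 20-mer anchor retrieval loses reads at
the Bernoulli rate 1-(1-r)^20, about 9.5% at r = 0.005 — the price of the
grep's perfect specificity.
"""

from fusiongrep import (
    AnchorSpec,
    ClassifierParams,
    SequencedRead,
    SimSource,
    SimulationConfig,
    build_fusion_transcript,
    call_junction,
    classify_read,
    evaluate_detection,
    scan_reads,
    simulate_library,
)
from fusiongrep.data import load_fixture_references

kat6a, crebbp = load_fixture_references()
fusion = build_fusion_transcript(kat6a, 3764, crebbp, 290)
cfg = SimulationConfig(
    seed=7,
    n_reads=50_000,
    substitution_rate=0.005,
    fusion_fraction=2e-4,
    sources=(
        SimSource("CREBBP_wt", crebbp.sequence, 0.7),
        SimSource("KAT6A_wt", kat6a.sequence, 0.3),
        SimSource("fusion", fusion, 1.0, junction=3764 - kat6a.coord_offset),
    ),
)
spec, params = AnchorSpec(), ClassifierParams()

reads, truth = simulate_library(cfg)
stream = [SequencedRead(r.read_id, r.sequence) for r in reads]
anchored = list(scan_reads(stream, spec))
classified = [classify_read(ar, [kat6a], crebbp, spec, params) for ar in anchored]
calls = call_junction(classified, [kat6a], crebbp)

m = evaluate_detection(
    truth, [a.read.read_id for a in anchored], classified, calls,
    cfg, spec, params, planted=(3764, 290),
)
expected = (1 - cfg.substitution_rate) ** 20
print(f"reads simulated:                {cfg.n_reads}")
print(f"anchor-covering reads:          {m.n_anchor_covered}")
print(f"retrieved by exact search:      {m.n_retrieved} "
      f"(sensitivity {m.retrieval_sensitivity:.4f}, Bernoulli expectation {expected:.4f})")
print(f"eligible junction reads:        {m.n_eligible_junction_reads}, "
      f"classified FUSION: {m.n_fusion_detected}")
print(f"false-positive FUSION calls:    {m.false_positive_fusions}")
print(f"junction calls at planted site: {m.junction_calls_correct}/{m.junction_calls_total}")
print(
    "meaning: even at ~10 junction reads in 50,000 the call lands exactly on\n"
    "the planted coordinates, while a single substitution inside the 20-mer\n"
    "anchor silently hides a read - the quantified sensitivity limit of grep."
)
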