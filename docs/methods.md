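# Methods

## Scope and model

`fusiongrep` implements targeted, alignment-free detection of a known fusion
transcript in raw RNA-seq reads. The object of study is a chimeric mRNA
joining a donor gene *D* to an acceptor gene *A* at exon boundaries; the
reference implementation targets the type-1 *KAT6A–CREBBP* fusion of
t(8;16)(p11;p13)-like AML, where *KAT6A* mRNA position 3764 (exon 16,
NM_006766.3 numbering) is joined to *CREBBP* position 290 (start of exon 2,
NM_004380.2 numbering). Every module works in 1-based inclusive mRNA
coordinates of the accessioned transcripts; genomic coordinates never enter.

The core assumption is that any read spanning the junction must contain the
first bases of the acceptor's first fused exon. An exact *k*-mer from that
exon (*k* = 20 here) therefore retrieves a complete, if error-censored,
superset of junction evidence: fusion reads, wild-type acceptor reads, and
any other sequence carrying the exon (e.g. unspliced genomic fragments).
Classification of the retrieved reads — not the retrieval — distinguishes
these.

## Retrieval

Exact substring search, forward strand by default; reverse-complement search
is an explicit option since strandedness of a library is protocol-dependent.
`N` never matches. On multiple anchor occurrences the leftmost is used and
flagged. Exactness is a design decision, not a shortcut: it reproduces the
grep operation the procedure is defined by, has perfect specificity for the
anchor, and its sensitivity loss is exactly Bernoulli, (1−r)^k per
anchor-covering read at substitution rate *r* (≈ 0.905 at r = 0.005,
k = 20). Approximate matching would change the operation being studied and
is deliberately out of scope.

## Split-read classification

For a retrieved read, let *U* be the flank upstream of the anchor and *V*
the downstream flank. All flank comparison is bounded-Hamming (no indels),
with budget ⌈ρ·L⌉ mismatches for a matched length *L*; ρ = 0.10 by default.
`N` counts as a mismatch. Base qualities are ignored.

**Downstream (acceptor) extension.** *V* is explained as: acceptor sequence
continuing from the anchor end, possibly followed by sequencing adapter
(3' read-through when the cDNA insert is shorter than the read), possibly
ending in terminal sequencing errors. Candidate explanations are enumerated:
every position where the adapter (default TruSeq stem `AGATCGGAAGAGC`,
minimum overlap 5; bases after a complete adapter clip with it) can begin,
plus no-clip. Each candidate is extended base by base and then trimmed to
the longest match-ending prefix whose mismatches fit the budget (this
reduces to trimming the trailing mismatch run in the ordinary case). The
winning candidate has the fewest mismatches, then the longest extension,
then the largest adapter clip. This two-level rule — maximal extension per
clip point, parsimony across clip points — is what simultaneously handles
the two ambiguous motifs seen in real junction-region reads: an internal
substitution followed by more matching sequence (extend through it) and an
adapter whose first base coincides with the next reference base (prefer the
longer reference extension when mismatch-free, the clean clip otherwise).

**Upstream hypothesis test.** Two hypotheses are scored: *wild-type* — *U*
matches the acceptor's own bases immediately before the anchor (position
forced, one comparison); *fusion* — *U* matches a suffix of some donor
reference ending at any position *e* (all placements scored; fewest
mismatches, ties to the largest *e*, i.e. the breakpoint closest to the
anchor). The fewest-mismatch hypothesis wins; an exact tie defaults to
wild-type (parsimony: no rearrangement) with an optional AMBIGUOUS mode.
No qualifying hypothesis yields OTHER; |U| below `min_upstream_flank`
(default 6 nt, below the shortest informative donor flank observed in
practice, 9 nt) yields UNINFORMATIVE. The donor search space is the supplied
reference set; de-novo partner discovery is a non-goal.

The defaults (ρ = 0.10, adapter stem with overlap ≥ 5, trailing-error
trimming, `min_upstream_flank` = 6) reproduce the published per-read span
annotations of all 26 junction-region reads exactly; the original
classification was manual and stated no tolerances.

**Junction calling and frame.** FUSION reads group by (donor accession,
breakpoint); support is the group size, ordering deterministic (support,
then accession, then coordinate). With CDS starts c_D and c_A known, donor
coding length L_D = e − c_D + 1 and acceptor offset L_A = s − c_A give:
in-frame iff L_D ≡ L_A (mod 3); junction codons ⌈L_D/3⌉ and ⌊L_A/3⌋ + 1.
A breakpoint upstream of the CDS yields frame = unknown. For the type-2
variant, whose junction interrupts acceptor codon 267, the acceptor
position is modeled one base into that codon (a junction at its first base
would be in frame, contradicting the variant's defining property).

## Reference handling and consensus reconstruction

References are (possibly partial) mRNA windows: sequence, `coord_offset`,
exon intervals, optional CDS start and cytoband, read from FASTA plus a
one-row-per-exon TSV. The packaged fixtures are **not** downloaded
sequences: they are rebuilt by per-column majority vote from the packaged
reads — wild-type reads aligned on the anchor reconstruct CREBBP 212–380;
fusion-read upstream flanks right-justified at the breakpoint reconstruct
KAT6A 3686–3764. Ties break lexicographically (A<C<G<T) and are reported as
low-confidence columns (none occur here); `N` does not vote. Fixture exon
intervals are clipped to the reconstructed windows, since only the
exon-1|exon-2 boundary at 289|290 is computationally load-bearing. Full
mRNA references (needed for in-silico PCR with the published primers and
for absolute codon numbers) are user-supplied one-time downloads; the
loader documents the expected files.

## In-silico PCR

The forward primer binds where it occurs in the template; the reverse
primer, written 5'→3' on the antisense strand per convention, binds where
its reverse complement occurs. Binding is exact by default (mismatch
tolerance opt-in); product length is rev-site end − fwd start + 1. A
verification PCR must have exactly one productive placement — zero or
multiple placements is an error, not a product. No thermodynamics (Tm,
dimers, efficiency) is modeled.

## Caller audit

Generic caller tables (TSV/CSV; pair column split on the last hyphen, or
two gene columns) are checked for a target pair under symbol aliases
(KAT6A = MYST3 = MOZ, CREBBP = CBP), orientation-insensitively. Cytoband
filtering keeps candidates whose partners map into the karyotype's
breakpoint bands (`any` or `both` mode; sub-band annotations like 16p13.3
match 16p13); unresolvable genes are dropped and counted. ISCN rendering
orders chromosomes 1–22, X, Y with bands following their chromosomes;
intrachromosomal pairs are rejected as not expressible as t(). The
gene→cytoband map is a user-supplied TSV with a small bundled default — no
live annotation service.

## Simulator

Single-end, sense-strand reads from weighted template transcripts, with a
fusion template at a fixed low fraction of the library. Per read: fragment
length from a normal distribution (mean 150, sd 30 by default) truncated to
[`insert_min` = 30, template length] — a transcript shorter than the target
insert fragments to itself, which is how the short reconstructed templates
remain usable; start uniform; the first `read_length` bases are copied and,
when the fragment is shorter than the read, adapter sequence fills the
remainder (reproducing 3' read-through tails of 5–24 nt as seen in real
junction-region reads). Substitutions are i.i.d. per template-derived base
(default 0.005), never in adapter fill; no indels — sufficient to exercise
the mismatch budgets and the exact-anchor sensitivity question, and noted
as future work. Constant base quality (qualities are ignored downstream).
The generator is numpy PCG64; a fixed seed gives byte-identical FASTQ.
Every read is ledgered (source, start, junction coverage and overhang,
errors, adapter bases), so evaluation is exact: retrieval sensitivity over
anchor-covering reads, classification sensitivity over junction reads with
a full anchor and sufficient donor overhang, false-positive count over
wild-type reads, and junction-coordinate accuracy.

Desk-scale defaults stand in for the original deep library (tens of
millions of reads, of which 11 in ~53 million carried the junction): the
property-based checks use 50,000 reads with fusion abundance 2×10⁻⁴, which
mirrors the ~10 supporting reads of the real case at a size where the
binomial test for retrieval sensitivity is tight (anchor-covering reads
number in the tens of thousands because the background is dominated by the
acceptor-transcript window). What passing these tests shows: the exact
arithmetic of retrieval loss, zero false-positive fusion classification at
default tolerances, and exact junction-coordinate recovery — under a
substitution-only error model on short reconstructed templates. What they
do not show: robustness to indels, strand mixtures, splice isoform
diversity, or expression-level realism.

## Numerical and degenerate-input choices

- Mismatch budget ⌈ρ·L⌉, evaluated on the matched length after clipping and
  trimming.
- All tie-breaks are deterministic and documented: consensus (lexicographic,
  flagged), suffix placement (largest end), downstream candidates
  (mismatches, then extension, then clip), hypothesis tie (wild-type).
- Empty downstream flank → acceptor span is the anchor itself; downstream
  matching always succeeds (worst case: everything trimmed), so every
  retrieved read gets a span and the bookkeeping identity
  donor + acceptor + adapter_clipped + trailing_trimmed = read length holds
  for FUSION and WILDTYPE reads.
- Empty read files, empty FUSION sets and header-only tables produce empty
  results, not errors; malformed inputs (annotation rows, duplicate ranks,
  out-of-window coordinates) fail loudly with locations.

## Known limitations

- Exact-anchor retrieval cannot see reads with any error in the anchor;
  this is quantified, not mitigated.
- Hamming-only flank matching: an indel near the junction would misclassify
  a read as OTHER rather than shift coordinates.
- The genomic (OTHER) category is a diagnosis of exclusion; no genome
  alignment is attempted.
- Reverse-complement retrieval is off by default; paired mates are scanned
  as independent streams and spanning-fragment (non-split) evidence is not
  used.
- The bundled references cover only the junction neighbourhoods; absolute
  codon numbering and published-primer PCR require the full mRNAs.
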