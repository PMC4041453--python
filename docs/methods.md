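# Methods

This note documents the models behind `vntrkit`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that matter for reproducing results.

## The locus model

The package targets kb-scale GC-rich tandem repeats (macrosatellites) of the
kind found at human 1q23.3: an array of n near-identical units of length u
(human unit 7380 bp; mouse homologue ~7.6 kb), each unit carrying a fixed set
of short conserved cassettes (five tRNA genes) and one 24-bp CTCF-binding
motif, flanked by LTR-annotated blocks, with no XbaI site inside the array so
a single digest fragment spans it. Allelic copy numbers range from 9 to ~43
units; families occasionally show germline (meiotic) size changes and somatic
(mitotic) third alleles.

## Synthetic-data generators

`LocusSpec` defaults are the study conditions: u = 7380 bp, n = 8 copies, 2%
per-base substitution divergence of each unit from a shared consensus,
unit GC 64.2%, flank GC 41% (the chromosome-average background), 10-kb
flanks, five cassettes plus one motif per unit, forbidden site `TCTAGA`
(XbaI) scrubbed from the array span.

Key modelling choices:

* **Substitution-only divergence.** Units never gain or lose bases, so unit
  length, phase, and every truth interval are exact. Real units also vary in
  microsatellite run lengths; an indel process would blur the period and the
  interval bookkeeping, so it is deliberately excluded (a
  `microsatellite_jitter` flag is reserved but off by default).
* **Protected elements.** Cassette and motif copies are pasted undiverged
  into every unit, mirroring the observation that the tRNA genes and the
  CTCF motif are the conserved parts of the unit. Consequence: arrays built
  with the default layout have expected inter-unit identity slightly above
  1 − 2d because ~400 bp per unit never mutate. Analyses that need the pure
  "expected identity = 1 − 2d" condition generate element-free units.
* **Placeholder cassettes.** The five shipped cassette sequences are frozen
  synthetic 72–87-bp sequences (tRNA-gene-sized), mutually free of shared
  11-mers and of XbaI sites. They are *stand-ins*: real tRNA gene sequences
  can be supplied as a `cassette_library`.
* **Forbidden-site scrubbing** resamples one random unprotected base inside
  each offending match (both strands considered) and iterates; this is
  bounded-time, unlike rejection sampling of whole sequences. A forbidden
  site wholly inside a protected element is an error, since the invariant
  cannot be satisfied without mutating the element.
* **Species pairs.** Two independent random scaffolds (default GC 0.60, an
  intermediate between the human 64.2% and mouse 54.5% unit GC) with the
  shared cassettes embedded identically in both, plus the two printed CTCF
  motif variants (human/mouse), one per scaffold. Elements are placed one
  per equal-width zone with seeded jitter, guaranteeing non-overlap.
* **Pedigrees.** Founders carry two allele copy numbers; children inherit
  one seeded choice per parent. A meiotic event adds a copy delta to one
  transmission; a mitotic event appends a third band. Band sizes are exact
  (`copies·u + flank`); measurement noise is applied separately (below).

Coordinates are 0-based half-open throughout; strands are `+`/`−`. All
generators are byte-reproducible per seed.

What the generators do **not** emulate: indel mutation, recombination-driven
unit shuffling, microsatellite expansion within units, hybridization
chemistry, partial digestion, or gel image formation. Passing tests on this
synthetic model therefore demonstrate correctness of the *computational*
pipeline under a clean substitution model, not performance on real sequence
with indels and segmental structure.

## Periodicity detection

`offset_spectrum(seq, k=16, min_period=500, max_period=50000)` counts pairs
of identical k-mers per offset. With k = 16, a random collision at a given
offset has probability ~4⁻¹⁶ per position pair, so a ~100-kb locus
contributes ≪ 1 chance count in total, while a 7.3-kb-unit array at 2%
divergence contributes thousands of true counts at u, 2u, 3u, …
(a 16-mer survives between two units with probability ≈ 0.96¹⁶ ≈ 0.5).
`estimate_unit_length` takes the maximal-count offset (ties toward the
smallest), collapses offsets that are integer multiples (±k bp) of a smaller
qualifying offset onto the fundamental period, and requires
`min_support = max(5, 5·L²/4^k)` counts — five times the expected chance
collision count, floored so a single random collision never qualifies.
No qualifying offset is a "no array" result (`None`), not an exception.

`locate_array` finds the maximal region whose density of offset-u k-mer
self-matches (smoothed over one unit length — a shorter window is distorted
by the identical embedded elements, which match at density ~1) exceeds half
the peak, then refines each boundary with a step statistic on *base-level*
offset-u identity: the boundary is the position maximizing the contrast
between the following and preceding windows (W = min(u/2, 256) bp) of
offset-u base matches. Base-level contrast is used because exact-k-mer
support breaks whenever a substitution falls within k bp of the array edge,
which at 2% divergence happens often enough to shift a k-mer-based boundary
by tens of bp. Measured on the default generator, refined boundaries fall
within ±14 bp of truth over 40 seeds (often exact). End-boundary ties are
broken toward the wider array.

Phase convention: the first unit starts at the detected array start.
Restriction-enzyme-defined monomer phases (EcoRV/XbaI cuts) are arbitrary
rotations of the same circular unit order and are not reproduced.

## Alignment and identity

`global_align` is an affine-gap Needleman–Wunsch/Gotoh DP (match +1,
mismatch −1, gap open −3, gap extend −1; a length-g gap costs
open + g·extend). The implementation is banded (vectorized per row; the
gap-in-a state is computed by a prefix-scan over run starts); `band=None`
explores the full matrix. Traceback tie-breaking is deterministic: diagonal,
then up (gap in b), then left. For 7.4-kb unit pairs that differ only by
substitutions the optimum lies on the main diagonal, so the default band of
200 columns returns the full-matrix optimum; band/full equivalence is
asserted in the tests on 2-kb diverged pairs, and the aligner is verified
against exhaustive alignment enumeration on short strings and against edlib
on long pairs.

Two identity conventions are exposed deliberately:

* `lcs_min_len` — maximum achievable aligned matches (LCS length) divided by
  the shorter sequence length. This reproduces the published short-motif
  convention: the mouse/human CTCF motifs (both 24 nt) share 22 matches →
  92% after half-up rounding.
* `alignment_columns` — matches over total columns of the optimal global
  alignment; used for unit-level identity matrices.

Consensus is column-majority over equal-length units (guaranteed by the
substitution-only decomposition), ties broken alphabetically. Unequal-length
input is rejected rather than silently padded.

## Composition

CpG obs/exp uses the standard formula count·N/(#C·#G) with N the sequence
length; it is defined as 0 when #C·#G = 0. CGI calling slides a 200-bp
window at step 1 (exact, affordable at unit scale), applies the classical
thresholds (GC ≥ 0.5, obs/exp ≥ 0.6), merges passing windows into maximal
intervals, and skips windows with >10% N. The published annotation pipeline
behind "extensive CpG island" does not state its parameters; the
Gardiner-Garden–Frommer values are the field's default. Repeat-class
enrichment is bp-coverage (union length within the region / region length)
against either an interval-derived or a published constant background; fold
is undefined (None) for a zero background.

## Virtual gel

* **Digestion** scans the top strand for the IUPAC site (both strands for
  non-palindromic sites, reported in top-strand coordinates); fragments
  always partition the input.
* **In-silico PCR** requires Hamming matches with an exact 3′-terminal base
  (polymerase extension is 3′-anchored); products are forward-primer match
  plus downstream reverse-complemented reverse-primer match within
  `max_len`, on both template orientations. Product length is the inclusive
  5′-to-5′ span. The shipped primer pair brackets a 519-bp amplicon.
* **Band noise** is multiplicative lognormal with unit mean and coefficient
  of variation `cv` (PFGE sizing error scales with size).
* **Copy calls**: n = ⌊(L − c)/u⌋ with defaults u = 7200, c = 0. This is the
  unique convention among the plausible unit sizes (7.2/7.3/7.38 kb) and
  rounding rules that reproduces all three published calls (70 kb → 9,
  200 kb → 27, 310 kb → 43) simultaneously; the published arithmetic itself
  is not stated. Both parameters are configurable.
* **Pedigree classification**: bands co-migrate when their relative
  difference is ≤ `rel_tol` (default 0.03). A >2-band member is a mitotic
  event; its somatic band — identified as the single band unexplained by the
  member's own typed parents, or, for founders, the band nearest another of
  the member's own bands — is excluded from transmission matching (founders
  keep all bands germline-eligible when the identification is ambiguous).
  A child band matching neither parent's germline bands is a meiotic event;
  meiotic calls require both parents typed.
* **Noise model for specificity.** Within a single blot, PFGE sizing error
  is dominated by shared ladder calibration, so the test harness derives the
  noise seed from (blot, true size): equal true sizes on one blot measure
  identically, and alleles ≥5 copies apart stay well separated at cv = 0.02.
  Under fully independent per-band noise, the ratio of two cv = 0.02
  measurements has ~2.8% sd, and any fixed tolerance near 3% would flag a
  large fraction of true transmissions — a property of the noise model, not
  of the classifier.

## Conserved islands

Seeds are exact 11-mers (the printed motif pair shares a 12-nt prefix, so
the conserved motif is seedable; shorter seeds inflate the chance-seed
count), extended ungapped under X-drop 12 with ±1 scoring. Extension
endpoints are the *farthest* position attaining the maximal running score;
the tie-break toward longer extension lets the extension cross the
motif pair's two compensating single-base indels and report the full 24-bp
element. Islands on diagonals within ±2 bp whose spans overlap (±2 bp) are
merged; island matches are recomputed as the LCS of the paired substrings
and identity as matches over the longer span, consistent with the
short-motif convention. When an island falls below the identity threshold,
its ends are trimmed (≤16 columns per side, in lockstep) to the
maximal-identity sub-span — X-drop endpoints overshoot short elements into
random flank, and trimming restores the element boundaries. Filters:
both spans ≥ 20 bp, identity ≥ 0.85.

**False-discovery characteristics (important).** With these thresholds the
detector recovers every embedded element (five identical cassettes + the
92%-identical motif) in 50/50 seeded pairs, but chance islands are *not*
rare: two independent ~7.4/7.6-kb GC-0.60 scaffolds contain on the order of
one 20-bp span pair at ≥85% LCS identity reachable from an 11-mer seed
(~40 chance seeds per pair; LCS identity of random 20-mers averages ~0.65
with sd wide enough that 0.85 is only ~2.7 sd out). Empirically the default
pipeline reports ~1–2 chance islands per random scaffold pair. This is
fundamental rather than implementational: the 24-bp/92% motif's ungapped
alignment score (~17) lies *inside* the score distribution of the best
chance islands at this search-space size, so no monotone score threshold
can keep the motif while rejecting all chance islands. Treat island lists
as candidates: elements supported by length ≫ 20 bp or identity ≈ 1 are
unambiguous; 20–25-bp islands at identity near 0.85 require orthogonal
evidence (positional homology, motif content). `scan_motif` provides that
orthogonal check for the CTCF element.

## Pipeline

`characterize_locus` chains detection → decomposition → composition →
digestion → copy calling → cassette census (consensus scanned against the
cassette library with ≤2 mismatches, both strands). The copy number is
reported under both the PFGE convention (u = 7200, c = 0) and the detected
unit length. Reports are JSON with a provenance block (tool version, input
paths, full parameter set); no timestamps, so identical inputs give
byte-identical reports.

Problem sizes used by the shipped analyses (chosen to keep any run
interactive on one CPU): arrays of 8–10 × 7380-bp units for recovery
analyses, 1.2-kb-unit surrogates for multi-seed invariant sweeps, 50 seeded
species pairs, 100 seeded pedigrees.

## Known limitations

* No indel divergence between units; real macrosatellite units drift in
  length, which would require anchored alignment rather than exact tiling.
* Consensus is column-majority, not a profile/MSA; it is only meaningful
  under the substitution-only model.
* The island detector's false-discovery behaviour at the default thresholds
  is material (see above); defaults favour sensitivity to the known
  conserved elements.
* Copy-number calling assumes complete digestion and a single
  array-containing fragment; partial digests and star activity are out of
  scope.
* Real-genome headline values (64.2% GC, 588 CpG per unit, LTR enrichment
  percentages, primate identities) depend on specific genome builds and
  annotations; the operations that compute such quantities are implemented
  and tested on synthetic/toy inputs, but those published numbers are not
  regression targets here.
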