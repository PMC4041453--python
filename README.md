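# vntrkit

Toolkit for characterizing **macrosatellites** — tandem repeats with kb-scale
units whose copy number varies between alleles (VNTRs). It was built around
the analysis of a GC-rich tRNA-gene tandem repeat on human chromosome 1q23.3:
an array of ~7.3-kb units (7380 bp), each carrying five tRNA genes and a
24-bp CTCF-binding motif, flanked by LTR elements, with 9–43 repeat units per
allele and occasional meiotic/mitotic size changes in families. The package
re-implements that locus characterization as reusable, tested components and
ships a synthetic-locus generator with known ground truth so every stage can
be validated end to end.

Audience: genomicists working on large tandem repeats who need desk-scale,
reproducible versions of the classic wet-lab/browser analyses — dot-plot-style
periodicity screens, PFGE Southern genotyping, CpG-island annotation, and
cross-species conservation scans.

## What it computes

* **Tandem-array detection** (`vntrkit.arraydetect`) — a k-mer self-match
  *offset spectrum*: every pair of identical k-mers at offset *d* votes for
  period *d*; the fundamental period is the maximal-count offset after
  harmonic collapsing. Array boundaries come from the span of offset-*u*
  self-matches; units are tiled from the array start and compared by banded
  affine-gap global alignment (`vntrkit.align`), giving a consensus and a
  pairwise identity matrix.
* **Composition** (`vntrkit.composition`) — GC fraction, CpG counts and
  observed/expected ratio (obs/exp = #CG · N / (#C · #G)), CpG-island calls
  with the Gardiner-Garden–Frommer criteria (200 bp, GC ≥ 50%, obs/exp ≥
  0.6), and bp-coverage repeat-class enrichment.
* **Virtual gel** (`vntrkit.gel`) — IUPAC restriction digestion, in-silico
  PCR with 3′-anchored primer matching, lognormal PFGE band-sizing noise,
  and the copy-number caller *n* = ⌊(L − c)/u⌋ that translates an
  array-containing fragment of size L into an integer repeat count (defaults
  u = 7200 bp, c = 0 reproduce the published 70 kb → 9, 200 kb → 27 and
  310 kb → ~43 calls). Pedigree band tables are screened for instability:
  >2 bands in one individual → mitotic (somatic) event; a child band
  matching no parental band (3% relative tolerance) → meiotic event.
* **Conservation** (`vntrkit.conservation`) — BLAST-style conserved-island
  discovery between two diverged repeat units (exact 11-mer seeds, ungapped
  X-drop extension, diagonal merging, length/identity filters) and IUPAC
  consensus-motif scanning on both strands. Island identity uses the
  max-matches convention (LCS / longer span), the same convention as the
  published "22 of 24 nucleotides" (92%) motif comparison.
* **Synthetic data** (`vntrkit.synthetic`) — seeded generators for loci
  (tandem array + flanks, embedded cassettes/motif, XbaI-free array body),
  three-generation pedigrees with optional instability events, and
  two-species repeat-unit pairs sharing a configurable set of conserved
  elements. Substitution-only divergence keeps unit length and phase exact
  ground truth.

## Worked example

Simulate the default locus (8 × 7380-bp units at 2% divergence, GC 0.642,
10-kb flanks) and characterize it:

```sh
vntrkit simulate-locus --seed 1 --out-prefix locus
vntrkit characterize locus.fa --annotations locus.truth.bed --out report.json
```

Key fields of `report.json` (abridged):

```json
{
  "array": {"start": 10000, "end": 69047, "unit_length": 7380,
            "copy_estimate": 8.0009},
  "decomposition": {"n_units": 8, "mean_offdiagonal_identity": 0.9605},
  "composition": {"unit_gc_fraction": 0.6363, "unit_cpg_count": 732,
                  "unit_cgi_intervals": [[0, 7380]]},
  "digest": {"enzyme": "XbaI", "largest_fragment": 65405},
  "copy_number": {"fragment_bp": 65405, "unit_bp": 7200, "copies": 9,
                  "copies_at_detected_unit": 8},
  "cassettes": {"cassettes_per_unit": 5}
}
```

Reading the numbers: the detector recovers the unit length exactly (7380 bp)
and places the array within a few bp of the simulated truth (10000–69040);
the 8 units share 96.1% mean pairwise identity, consistent with the 2%
per-unit divergence (expected ≈ 1 − 2·0.02); the whole unit is called as one
CpG island; XbaI (absent from the array body by construction) releases the
array on a single 65.4-kb fragment, which the PFGE convention (u = 7200)
calls as 9 copies — and as 8 copies at the detected 7380-bp unit; and all
five tRNA-gene cassettes are found once per unit consensus.

Compare two species' repeat units and scan for the conserved CTCF motif:

```sh
vntrkit simulate-pair --seed 11 --out-prefix pair
vntrkit compare-units pair.a.fa pair.b.fa --out-prefix pair
```

## Layout

```
src/vntrkit/
  synthetic.py     seeded generators + ground truth (FASTA/BED/TSV writers)
  arraydetect.py   offset spectrum, unit-length estimate, boundaries, decomposition
  align.py         banded affine-gap aligner, LCS, identity conventions, consensus
  composition.py   GC/CpG/CGI statistics, interval coverage and enrichment
  gel.py           digestion, in-silico PCR, band noise, copy calls, pedigrees
  conservation.py  conserved-island discovery, motif scanning
  pipeline.py      end-to-end reports (characterize, genotype, compare)
  cli.py           `vntrkit` command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
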