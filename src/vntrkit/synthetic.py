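"""Seeded synthetic loci, pedigrees, and two-species unit pairs with ground truth.

The generators emulate a GC-rich macrosatellite of ~7.3–7.6-kb units arranged
in tandem: every unit carries five short gene cassettes (placeholders standing
in for the tRNA genes; users may supply real ones) and one conserved 24-bp
CTCF-motif element, the array body is kept free of a chosen restriction site
(XbaI by default) so a single digest fragment spans the whole array, and the
flanks carry LTR-like annotation blocks.  Divergence between units is
substitution-only, so unit length and phase are exact ground truth.

All generators are deterministic per seed: the same spec yields a
byte-identical sequence and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import iupac_regex, revcomp

#: The two printed 24-nt CTCF-motif sequences at the human and mouse loci.
HUMAN_CTCF_MOTIF = "CGAGAGCGCCCCCAGAGGCAGGCG"
MOUSE_CTCF_MOTIF = "CGAGAGCGCCCCAGAGGAAAGGCG"

#: Primers of the 519-bp probe amplicon used for genotyping blots.
PROBE_FWD_PRIMER = "CCGCGACCCTCTACCAATTG"
PROBE_REV_PRIMER = "TGCTCAGCGGTCAGAAGTTG"
PROBE_AMPLICON_BP = 519

#: Placeholder cassette library: five synthetic 72–87-bp sequences standing in
#: for the tRNA genes of a repeat unit (two sense, three antisense in the
#: default layout).  They are frozen random sequences, mutually free of shared
#: 11-mers and of XbaI sites; swap in real tRNA gene sequences as needed.
DEFAULT_CASSETTES: dict[str, str] = {
    "tRNA-Leu": "TAGAAAACGCCTTAGCGGCATTGACCAGATACCGCCGCAGACCCGAGGCGGCGCCCTTGGCCCGCCCTCAGCCACGGCCCTGG",
    "tRNA-Gly-1": "TAGGTTGGAGTTGTACGCAGAGGAGGGGATCGATCCGAAAGTTTCCGGAGTACTGGGTCGGCAACCCAGGGC",
    "tRNA-Glu": "CGACGACTACGCCCCATGTGGTCACTACCCGAGCAGGCCCCATTGTTAGTGGGTGCCTCTCCAAGAGATATCCA",
    "tRNA-Gly-2": "CGAGCGCAAACCACAGGGTACCGAGGAAATAACCTGCCTTTTGCCAAGGCTTTTCGGCCGGCGCCGGTATAT",
    "tRNA-Asp": "AGTGGAACTAGAGGAAGTCGGTGCCGCATTGAAAGACGTGGACGTGGACTGAAGGGTGGTTCTCGGTGCCCAGCA",
}

#: Default per-unit layout: (offset within unit, cassette id, strand).
DEFAULT_CASSETTE_POSITIONS: tuple[tuple[int, str, str], ...] = (
    (950, "tRNA-Leu", "+"),
    (2100, "tRNA-Gly-1", "+"),
    (3400, "tRNA-Glu", "-"),
    (4650, "tRNA-Gly-2", "-"),
    (5900, "tRNA-Asp", "-"),
)

DEFAULT_MOTIF_OFFSET = 6600
LTR_BLOCK_BP = 400  # annotated LTR-like block on each side, abutting the array

TRUTH_CLASSES = ("cassette", "motif", "LTR-like", "unit-boundary")


class GenerationError(RuntimeError):
    """A generator invariant cannot be satisfied for the given spec."""


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of a synthetic tandem-array locus.

    Defaults emulate the human 1q23.3-style locus: 7380-bp units, GC 64.2%,
    2% substitution divergence from the consensus, five cassettes plus one
    24-bp motif per unit, XbaI-free array body, and 10-kb flanks at the
    chromosome-average GC of 41%.
    """

    unit_length: int = 7380
    copy_number: int = 8
    divergence: float = 0.02
    gc_fraction: float = 0.642
    cassette_positions: tuple[tuple[int, str, str], ...] = DEFAULT_CASSETTE_POSITIONS
    motif_offset: int | None = DEFAULT_MOTIF_OFFSET
    motif: str = HUMAN_CTCF_MOTIF
    flank_length: int = 10000
    flank_gc: float = 0.41
    forbidden_site: str | None = "TCTAGA"
    microsatellite_jitter: bool = False  # optional length variation, off: keeps period exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")
        ivs = sorted((off, off + len(self._element_seq(cid)), cid)
                     for off, cid, _ in self.cassette_positions)
        if self.motif_offset is not None:
            ivs = sorted(ivs + [(self.motif_offset,
                                 self.motif_offset + len(self.motif), "motif")])
        prev_end = 0
        for start, end, cid in ivs:
            if start < 0 or end > self.unit_length:
                raise ValueError(f"element {cid!r} outside [0, unit_length)")
            if start < prev_end:
                raise ValueError(f"element {cid!r} overlaps the previous element")
            prev_end = end

    def _element_seq(self, cassette_id: str) -> str:
        return DEFAULT_CASSETTES.get(cassette_id, "")


@dataclass
class TruthAnnotation:
    """Ground-truth intervals on a generated sequence (0-based half-open)."""

    intervals: list[tuple[int, int, str, str]] = field(default_factory=list)

    def of_class(self, label: str) -> list[tuple[int, int, str, str]]:
        return [iv for iv in self.intervals if iv[2] == label]

    def sort(self) -> None:
        self.intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))

    def validate(self, seq_len: int) -> None:
        prev = -1
        for start, end, label, strand in self.intervals:
            if not (0 <= start < end <= seq_len):
                raise ValueError(f"interval ({start},{end}) out of bounds")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if start < prev:
                raise ValueError("intervals not sorted")
            prev = start

    def to_bed(self, path, chrom: str = "synthetic") -> None:
        with open(path, "w") as fh:
            for start, end, label, strand in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree of typed members with founder allele copy numbers.

    ``members`` lists (id, mother_id or None, father_id or None); founders
    (both parents None) must appear in ``founder_alleles`` with two copy
    numbers.  Optional events: ``meiotic_event=((parent_id, child_id),
    copy_delta)`` alters the copy number transmitted from that parent;
    ``mitotic_event=(member_id, extra_copies)`` gives that member a third
    band (somatic mosaicism).
    """

    members: tuple[tuple[str, str | None, str | None], ...]
    founder_alleles: dict[str, tuple[int, int]] = field(default_factory=dict)
    meiotic_event: tuple[tuple[str, str], int] | None = None
    mitotic_event: tuple[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate member ids")
        known = set(ids)
        for mid, mo, fa in self.members:
            for p in (mo, fa):
                if p is not None and p not in known:
                    raise ValueError(f"unknown parent {p!r} of {mid!r}")
            if (mo is None) != (fa is None):
                raise ValueError(f"member {mid!r} must have both parents or none")
            if mo is None and mid not in self.founder_alleles:
                raise ValueError(f"founder {mid!r} missing from founder_alleles")
        # acyclicity via topological ordering
        self._topo_order()

    def _topo_order(self) -> list[tuple[str, str | None, str | None]]:
        done: set[str] = set()
        order = []
        pending = list(self.members)
        while pending:
            progressed = False
            rest = []
            for m in pending:
                mid, mo, fa = m
                if mo is None or (mo in done and fa in done):
                    order.append(m)
                    done.add(mid)
                    progressed = True
                else:
                    rest.append(m)
            if not progressed:
                raise ValueError("pedigree parent links are cyclic")
            pending = rest
        return order


@dataclass(frozen=True)
class SpeciesPairSpec:
    """Two diverged scaffolds sharing a set of embedded conserved elements.

    Defaults emulate the human (7380 bp) vs mouse (7600 bp) repeat-unit
    comparison: five identical cassettes plus one near-identical 24-bp motif
    (the printed human/mouse CTCF sequences) embedded in otherwise
    independent GC-rich scaffolds.
    """

    unit_length_a: int = 7380
    unit_length_b: int = 7600
    shared_cassettes: tuple[str, ...] = tuple(DEFAULT_CASSETTES.values())
    shared_motif_a: str | None = HUMAN_CTCF_MOTIF
    shared_motif_b: str | None = MOUSE_CTCF_MOTIF
    scaffold_gc: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.shared_motif_a is None) != (self.shared_motif_b is None):
            raise ValueError("shared motifs must be given for both or neither")
        n = len(self.shared_cassettes) + (self.shared_motif_a is not None)
        if n:
            for L, name in ((self.unit_length_a, "a"), (self.unit_length_b, "b")):
                need = sum(len(c) for c in self.shared_cassettes)
                if self.shared_motif_a is not None:
                    need += max(len(self.shared_motif_a), len(self.shared_motif_b))
                if need > L:
                    raise GenerationError(
                        f"shared elements do not fit in scaffold {name}")


# ---------------------------------------------------------------------------


def make_background(length: int, gc_fraction: float, seed: int) -> str:
    """Random DNA of the given length and expected GC content.

    G and C are drawn with probability gc_fraction (split evenly), A and T
    with the remainder (split evenly).
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return codes_to_str(codes)


def codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes.astype(np.uint8)].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, protected: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Substitution-only mutation at the given per-base rate, sparing
    protected positions.  Substituted bases are drawn uniformly from the
    three alternatives."""
    out = codes.copy()
    hit = (rng.random(len(codes)) < rate) & ~protected
    idx = np.nonzero(hit)[0]
    if len(idx):
        out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def make_locus(spec: LocusSpec,
               cassette_library: dict[str, str] | None = None
               ) -> tuple[str, TruthAnnotation]:
    """Generate a tandem-array locus and its ground-truth annotation.

    The sequence is ``flank + copy_number diverged copies of a consensus unit
    + flank``; cassettes and the motif are copied undiverged at their unit
    offsets.  The forbidden restriction site is scrubbed from the array span
    (both strands) by resampling single bases outside protected elements.
    """
    lib = dict(DEFAULT_CASSETTES if cassette_library is None else cassette_library)
    rng = np.random.default_rng(spec.seed)
    u = spec.unit_length

    # consensus unit with protected elements pasted in
    at, gc = (1 - spec.gc_fraction) / 2, spec.gc_fraction / 2
    cons = rng.choice(4, size=u, p=[at, gc, gc, at])
    protected = np.zeros(u, dtype=bool)
    elements: list[tuple[int, int, str, str]] = []  # unit-relative truth
    from ._seq import encode
    for off, cid, strand in spec.cassette_positions:
        if cid not in lib:
            raise ValueError(f"cassette id {cid!r} not in library")
        cseq = lib[cid] if strand == "+" else revcomp(lib[cid])
        cons[off:off + len(cseq)] = encode(cseq)
        protected[off:off + len(cseq)] = True
        elements.append((off, off + len(cseq), "cassette", strand))
    if spec.motif_offset is not None:
        mo = spec.motif_offset
        cons[mo:mo + len(spec.motif)] = encode(spec.motif)
        protected[mo:mo + len(spec.motif)] = True
        elements.append((mo, mo + len(spec.motif), "motif", "+"))

    units = [_mutate(cons, spec.divergence, protected, rng)
             for _ in range(spec.copy_number)]

    fat, fgc = (1 - spec.flank_gc) / 2, spec.flank_gc / 2
    fl = spec.flank_length
    lflank = rng.choice(4, size=fl, p=[fat, fgc, fgc, fat])
    rflank = rng.choice(4, size=fl, p=[fat, fgc, fgc, fat])
    codes = np.concatenate([lflank] + units + [rflank])

    array_start, array_end = fl, fl + spec.copy_number * u
    prot_abs = np.zeros(len(codes), dtype=bool)
    for i in range(spec.copy_number):
        prot_abs[array_start + i * u: array_start + (i + 1) * u] = protected
    seq = codes_to_str(codes)

    if spec.forbidden_site:
        seq = _scrub_forbidden(seq, spec.forbidden_site, array_start, array_end,
                               prot_abs, rng)

    truth = TruthAnnotation()
    if fl >= LTR_BLOCK_BP:
        truth.intervals.append((array_start - LTR_BLOCK_BP, array_start,
                                "LTR-like", "+"))
        truth.intervals.append((array_end, array_end + LTR_BLOCK_BP,
                                "LTR-like", "+"))
    for i in range(spec.copy_number):
        base = array_start + i * u
        truth.intervals.append((base, base + u, "unit-boundary", "+"))
        for s, e, label, strand in elements:
            truth.intervals.append((base + s, base + e, label, strand))
    truth.sort()
    truth.validate(len(seq))
    return seq, truth


def _scrub_forbidden(seq: str, site: str, array_start: int, array_end: int,
                     protected: np.ndarray, rng: np.random.Generator,
                     max_rounds: int = 100) -> str:
    """Remove every occurrence of the IUPAC site (either strand) overlapping
    the array span by resampling single unprotected bases."""
    patterns = [iupac_regex(site)]
    rc = revcomp(site)
    if rc != site.upper():
        patterns.append(iupac_regex(rc))
    chars = list(seq)
    for _ in range(max_rounds):
        hits = []
        window = "".join(chars)
        for pat in patterns:
            for m in pat.finditer(window, max(0, array_start - len(site)),
                                  min(len(chars), array_end + len(site))):
                if m.start() < array_end and m.end() > array_start:
                    hits.append((m.start(), m.end()))
        if not hits:
            return "".join(chars)
        for s, e in hits:
            cand = [p for p in range(max(s, array_start), min(e, array_end))
                    if not protected[p]]
            if not cand:
                raise GenerationError(
                    f"forbidden site {site} lies inside a protected element")
            p = int(rng.choice(cand))
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[int(rng.integers(0, 3))]
    raise GenerationError(f"could not scrub forbidden site {site}")


def make_pedigree(spec: PedigreeSpec, unit_bp: int, flank_bp: int = 0):
    """Simulate band sizes through a pedigree with Mendelian transmission.

    Each member carries two germline alleles (copy numbers); non-founders
    inherit one allele from each parent chosen at random (seeded).  The
    optional meiotic event alters one transmission by ``copy_delta``; the
    optional mitotic event appends a third band to the named member.  Band
    sizes are exact predicted allele sizes in bp (add measurement noise with
    :func:`vntrkit.gel.simulate_band` if desired).
    """
    from .gel import Member, Pedigree, predict_allele_size

    rng = np.random.default_rng(spec.seed)
    order = spec._topo_order()
    alleles: dict[str, tuple[int, int]] = {}
    members: dict[str, Member] = {}
    for mid, mo, fa in order:
        if mo is None:
            a, b = spec.founder_alleles[mid]
        else:
            a = int(alleles[mo][rng.integers(0, 2)])
            b = int(alleles[fa][rng.integers(0, 2)])
            if spec.meiotic_event is not None:
                (par, child), delta = spec.meiotic_event
                if child == mid:
                    if par == mo:
                        a = a + delta
                    elif par == fa:
                        b = b + delta
                    else:
                        raise ValueError(
                            f"meiotic event parent {par!r} is not a parent of {mid!r}")
                    if min(a, b) < 1:
                        raise ValueError("meiotic event drives copies below 1")
        alleles[mid] = (a, b)
        bands = [float(predict_allele_size(a, unit_bp, flank_bp)),
                 float(predict_allele_size(b, unit_bp, flank_bp))]
        members[mid] = Member(mid, mo, fa, bands)
    if spec.mitotic_event is not None:
        mid, extra = spec.mitotic_event
        if mid not in members:
            raise ValueError(f"mitotic event names unknown member {mid!r}")
        members[mid].bands.append(
            float(predict_allele_size(extra, unit_bp, flank_bp)))
    return Pedigree(members=members)


def make_species_pair(spec: SpeciesPairSpec
                      ) -> tuple[str, str, tuple[TruthAnnotation, TruthAnnotation]]:
    """Two independent random scaffolds sharing embedded conserved elements.

    Each shared cassette is embedded identically in both scaffolds; the two
    motif variants are embedded one per scaffold.  Elements are placed one
    per equal-width zone with seeded jitter, so they never overlap.  Truth
    annotations list the shared-element intervals in each sequence, in the
    same pairing order.
    """
    rng = np.random.default_rng(spec.seed)
    elements: list[tuple[str, str, str]] = [
        (c, c, "cassette") for c in spec.shared_cassettes]
    if spec.shared_motif_a is not None:
        elements.append((spec.shared_motif_a, spec.shared_motif_b, "motif"))

    at, gc = (1 - spec.scaffold_gc) / 2, spec.scaffold_gc / 2
    out_seqs: list[str] = []
    out_truth: list[TruthAnnotation] = []
    from ._seq import encode
    for which, L in ((0, spec.unit_length_a), (1, spec.unit_length_b)):
        codes = rng.choice(4, size=L, p=[at, gc, gc, at])
        truth = TruthAnnotation()
        k = len(elements)
        if k:
            zone = L // k
            for i, (ea, eb, label) in enumerate(elements):
                eseq = (ea, eb)[which]
                room = zone - len(eseq)
                if room < 0:
                    raise GenerationError(
                        "shared elements overlap: scaffold too short for "
                        "non-overlapping placement")
                off = i * zone + int(rng.integers(0, room + 1))
                codes[off:off + len(eseq)] = encode(eseq)
                truth.intervals.append((off, off + len(eseq), label, "+"))
        truth.sort()
        truth.validate(L)
        out_seqs.append(codes_to_str(codes))
        out_truth.append(truth)
    return out_seqs[0], out_seqs[1], (out_truth[0], out_truth[1])


def make_amplicon_template(flank_bp: int = 500, gc_fraction: float = 0.642,
                           seed: int = 0,
                           fwd: str = PROBE_FWD_PRIMER,
                           rev: str = PROBE_REV_PRIMER,
                           product_bp: int = PROBE_AMPLICON_BP) -> str:
    """A template carrying the probe-amplicon primer pair at truth spacing.

    The forward primer and the reverse complement of the reverse primer are
    embedded so that the predicted product length equals ``product_bp``
    (519 bp for the default printed primers).
    """
    if product_bp < len(fwd) + len(rev):
        raise ValueError("product_bp shorter than the two primers")
    rng = np.random.default_rng(seed)
    L = product_bp + 2 * flank_bp
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    codes = rng.choice(4, size=L, p=[at, gc, gc, at])
    from ._seq import encode
    codes[flank_bp:flank_bp + len(fwd)] = encode(fwd)
    tail = revcomp(rev)
    end = flank_bp + product_bp
    codes[end - len(tail):end] = encode(tail)
    return codes_to_str(codes)


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(path, records: dict[str, str], wrap: int = 60) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_pedigree_tsv(path, pedigree) -> None:
    """TSV: member_id, mother_id, father_id, band_bp (semicolon-separated)."""
    with open(path, "w") as fh:
        fh.write("member_id\tmother_id\tfather_id\tband_bp\n")
        for m in pedigree.members.values():
            bands = ";".join(f"{b:.0f}" for b in m.bands)
            fh.write(f"{m.id}\t{m.mother or '.'}\t{m.father or '.'}\t{bands}\n")
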