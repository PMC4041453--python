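"""In-silico restriction digestion, PCR, PFGE band sizing, copy-number calls,
and pedigree instability classification.

The genotyping model: a restriction enzyme without sites in the tandem array
(XbaI here) releases the whole array on a single fragment, so the pulsed-field
band size L of that fragment translates to an integer repeat copy number
``floor((L - c) / u)`` for unit size u and flanking offset c.  The default
caller convention (u = 7200 bp, c = 0, floor) is the unique one among the
plausible unit sizes and rounding rules that reproduces the published calls
70 kb -> 9, 200 kb -> 27 and 310 kb -> ~43 copies simultaneously.

Pedigree classification compares band sizes with a relative tolerance (gel
sizing error scales with fragment size): a member with more than two bands is
somatically mosaic (mitotic instability); a child band matching no parental
band is a germline size change (meiotic instability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, is_palindromic, iupac_regex, revcomp

DEFAULT_UNIT_BP = 7200
DEFAULT_REL_TOL = 0.03


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")


BUILTIN_ENZYMES: dict[str, Enzyme] = {
    "XbaI": Enzyme("XbaI", "TCTAGA", 1),    # T^CTAGA
    "EcoRV": Enzyme("EcoRV", "GATATC", 3),  # GAT^ATC
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),  # G^AATTC
}


def digest(seq: str, enzyme: Enzyme) -> list[tuple[int, int]]:
    """Fragments of a linear sequence after complete digestion.

    Cut positions come from every top-strand match of the IUPAC site; for
    non-palindromic sites the bottom strand is scanned as well (reported as
    top-strand coordinates).  Fragments partition the input: their lengths
    always sum to the sequence length.
    """
    cuts: set[int] = set()
    pat = iupac_regex(enzyme.recognition)
    site_len = len(enzyme.recognition)
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            break
        cuts.add(m.start() + enzyme.cut_offset)
        pos = m.start() + 1
    if not is_palindromic(enzyme.recognition):
        pat_rc = iupac_regex(revcomp(enzyme.recognition))
        pos = 0
        while True:
            m = pat_rc.search(seq, pos)
            if m is None:
                break
            cuts.add(m.start() + (site_len - enzyme.cut_offset))
            pos = m.start() + 1
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def fragment_sizes(seq: str, enzyme: Enzyme) -> list[int]:
    return [e - s for s, e in digest(seq, enzyme)]


@dataclass
class PcrProduct:
    start: int          # 5' position of the leftmost primer on the top strand
    end: int            # half-open end (5' of the rightmost primer + 1)
    strand: str         # '+' if fwd anneals to the top strand, else '-'
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _primer_hits(template8: np.ndarray, primer: str, max_mm: int,
                 exact_3prime_at: str) -> list[tuple[int, int]]:
    """(position, mismatches) of Hamming matches of ``primer`` on the coded
    template; ``exact_3prime_at`` is 'last' or 'first' — the template base
    that must match exactly (the primer's 3' terminus)."""
    p8 = encode(primer)
    k = len(p8)
    L = len(template8)
    if L < k:
        return []
    win = np.lib.stride_tricks.sliding_window_view(template8, k)
    mm = (win != p8[None, :]).sum(axis=1)
    anchor = win[:, -1] == p8[-1] if exact_3prime_at == "last" else win[:, 0] == p8[0]
    ok = np.nonzero((mm <= max_mm) & anchor)[0]
    return [(int(i), int(mm[i])) for i in ok]


def insilico_pcr(template: str, fwd: str, rev: str, max_mm: int = 0,
                 max_len: int = 20000) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a linear template.

    A product is reported for every forward-primer match on the top strand
    paired with a downstream reverse-complemented reverse-primer match
    within ``max_len`` (and symmetrically with the roles swapped, covering
    products whose forward primer anneals to the bottom strand).  Primer
    matches allow up to ``max_mm`` Hamming mismatches but the 3'-terminal
    base must match.  Product length is the inclusive span between the two
    primer 5' positions.
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    t8 = encode(template)
    products: list[PcrProduct] = []
    for a, b, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
        a_hits = _primer_hits(t8, a, max_mm, "last")
        b_hits = _primer_hits(t8, revcomp(b), max_mm, "first")
        for a_pos, a_mm in a_hits:
            for b_pos, b_mm in b_hits:
                end = b_pos + len(b)
                if b_pos >= a_pos and 0 < end - a_pos <= max_len:
                    fwd_mm, rev_mm = (a_mm, b_mm) if strand == "+" else (b_mm, a_mm)
                    products.append(PcrProduct(a_pos, end, strand, fwd_mm, rev_mm))
    products.sort(key=lambda p: (p.start, p.end, p.strand))
    return products


def simulate_band(true_bp: float, cv: float, seed: int) -> float:
    """A measured band size with multiplicative lognormal sizing error.

    The error has unit mean and coefficient of variation ``cv`` (cv=0
    returns the true size unchanged).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return float(true_bp)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(true_bp * rng.lognormal(-sigma * sigma / 2, sigma))


def call_copies(fragment_bp: float, unit_bp: float = DEFAULT_UNIT_BP,
                flank_bp: float = 0) -> int:
    """Integer repeat copy number of an array-containing fragment:
    floor((fragment_bp - flank_bp) / unit_bp)."""
    if unit_bp <= 0:
        raise ValueError("unit_bp must be positive")
    if fragment_bp < flank_bp:
        raise ValueError("fragment smaller than the flanking offset")
    return int(math.floor((fragment_bp - flank_bp) / unit_bp))


def predict_allele_size(copies: int, unit_bp: float = DEFAULT_UNIT_BP,
                        flank_bp: float = 0) -> float:
    """Expected fragment size of an allele: copies * unit_bp + flank_bp."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return copies * unit_bp + flank_bp


# ---------------------------------------------------------------------------
# pedigrees


@dataclass
class Member:
    id: str
    mother: str | None
    father: str | None
    bands: list[float] = field(default_factory=list)


@dataclass
class Pedigree:
    members: dict[str, Member]

    def validate(self) -> None:
        for m in self.members.values():
            if not m.bands:
                raise ValueError(f"member {m.id!r} has no bands")
            if len(m.bands) > 3:
                raise ValueError(f"member {m.id!r} has more than 3 bands")


@dataclass
class InstabilityEvent:
    kind: str            # 'meiotic' | 'mitotic'
    member_id: str
    band_bp: float
    explanation: str


def bands_match(a: float, b: float, rel_tol: float) -> bool:
    """Two bands co-migrate if their relative size difference is within
    rel_tol (gel sizing error scales with fragment size)."""
    return abs(a - b) / max(a, b) <= rel_tol


def classify_pedigree(ped: Pedigree,
                      rel_tol: float = DEFAULT_REL_TOL) -> list[InstabilityEvent]:
    """Flag meiotic and mitotic instability events in a typed pedigree.

    A member with more than two bands is reported as a mitotic event.  For
    transmission matching, a 3-band member's somatic (extra) band is the one
    unexplained by its own parents when those are typed; founders keep all
    bands as potentially germline.  A child band (excluding its own somatic
    band) that matches no germline band of either parent is reported as a
    meiotic event; meiotic calls are only made for members with both parents
    typed.
    """
    if not 0 < rel_tol <= 0.1:
        raise ValueError("rel_tol must be in (0, 0.1]")
    ped.validate()
    events: list[InstabilityEvent] = []
    somatic: dict[str, float] = {}

    def parents_typed(m: Member) -> bool:
        return (m.mother in ped.members and m.father in ped.members)

    for m in ped.members.values():
        if len(m.bands) > 2:
            extra: float | None = None
            if parents_typed(m):
                parental = (ped.members[m.mother].bands
                            + ped.members[m.father].bands)
                unexplained = [b for b in m.bands
                               if not any(bands_match(b, p, rel_tol)
                                          for p in parental)]
                if len(unexplained) == 1:
                    extra = unexplained[0]
            if extra is None:
                # founder (or ambiguous): take the band closest to another of
                # the member's own bands as the somatic variant
                def nearest_gap(i: int) -> float:
                    b = m.bands[i]
                    return min(abs(b - o) / max(b, o)
                               for j, o in enumerate(m.bands) if j != i)
                extra = m.bands[min(range(len(m.bands)), key=nearest_gap)]
            somatic[m.id] = extra
            events.append(InstabilityEvent(
                "mitotic", m.id, extra,
                f"{len(m.bands)} bands: somatic mosaicism"))

    def germline(mid: str) -> list[float]:
        mem = ped.members[mid]
        if mid in somatic:
            out = list(mem.bands)
            out.remove(somatic[mid])
            return out
        return mem.bands

    for m in ped.members.values():
        if not parents_typed(m):
            continue
        parental = germline(m.mother) + germline(m.father)
        child_bands = [b for b in m.bands
                       if m.id not in somatic or b != somatic[m.id]]
        for b in child_bands:
            if not any(bands_match(b, p, rel_tol) for p in parental):
                events.append(InstabilityEvent(
                    "meiotic", m.id, b,
                    "band matches no parental allele: germline size change"))
    return events


def read_band_table(path, size_unit: str = "kb"):
    """Read a band table TSV (member_id, band sizes semicolon-separated).

    Returns a list of (member_id, [band_bp, ...]).  ``size_unit`` is the unit
    of the stored sizes ('kb' for cohort tables, 'bp' for pedigree files).
    """
    scale = 1000.0 if size_unit == "kb" else 1.0
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        id_col = 0
        band_col = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            raw = fields[band_col]
            bands = []
            for tok in raw.split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                try:
                    bands.append(float(tok) * scale)
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric band {tok!r}")
            out.append((fields[id_col], bands))
    return out
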