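"""Cross-species conserved-island discovery and consensus-motif scanning.

Conserved islands between two diverged sequences are found BLAST-style: exact
k-mer seeds (both strands of the second sequence) are extended without gaps in
both directions under an X-drop rule (+1 match / -1 mismatch), trimmed back to
their maximal-score endpoints, merged across near-identical diagonals, and
filtered by minimum length and identity.  Island identity is the maximal
number of identical aligned nucleotides (LCS) between the paired substrings
divided by the longer span, the same convention used for short-motif identity
("22 of 24 nucleotides"); computing it over the merged span lets an element
interrupted by one or two single-base indels — the conserved CTCF motif is
the motivating case — be reported as a single island.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .align import lcs_matches, pairwise_identity
from ._seq import encode, iupac_allowed_matrix, revcomp


@dataclass
class ConservedIsland:
    """A paired high-identity segment (0-based half-open, both sequences)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    identity: float
    strand: str

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_start


@dataclass
class MotifMatch:
    position: int
    strand: str
    mismatches: int


def _xdrop_extend(a8: np.ndarray, b8: np.ndarray, i: int, j: int, k: int,
                  xdrop: float, match: float = 1.0, mismatch: float = -1.0
                  ) -> tuple[int, int]:
    """Ungapped X-drop extension of a seed at (i, j) of length k.

    Returns (left, right): columns added on each side, each trimmed to the
    farthest position attaining the maximal running score (ties broken
    toward the longer extension).
    """
    best = 0.0
    score = 0.0
    left = best_left = 0
    p, q = i - 1, j - 1
    while p >= 0 and q >= 0:
        score += match if (a8[p] == b8[q] and a8[p] < 4) else mismatch
        left += 1
        if score >= best:
            best, best_left = score, left
        if score < best - xdrop:
            break
        p, q = p - 1, q - 1
    best = 0.0
    score = 0.0
    right = best_right = 0
    p, q = i + k, j + k
    n, m = len(a8), len(b8)
    while p < n and q < m:
        score += match if (a8[p] == b8[q] and a8[p] < 4) else mismatch
        right += 1
        if score >= best:
            best, best_right = score, right
        if score < best - xdrop:
            break
        p, q = p + 1, q + 1
    return best_left, best_right


def find_conserved_islands(a: str, b: str, k: int = 11, xdrop: float = 12,
                           min_len: int = 20, min_identity: float = 0.85,
                           diagonal_window: int = 2) -> list[ConservedIsland]:
    """Conserved islands between two sequences (both strands of ``b``).

    Exact k-mer seeds are extended ungapped under X-drop; islands on the same
    (or near-identical, within ``diagonal_window``) diagonals whose spans
    overlap or nearly abut are merged; merged islands are filtered by
    ``min_len`` (both spans) and ``min_identity`` (LCS matches over the
    longer span).  Output is sorted by position in ``a``.
    """
    if k > min_len:
        raise ValueError("k must not exceed min_len")
    a8 = encode(a)
    islands: list[ConservedIsland] = []
    for strand, bs in (("+", b), ("-", revcomp(b))):
        b8 = encode(bs)
        raw = _strand_islands(a8, b8, k, xdrop)
        merged = _merge_diagonal(raw, diagonal_window)
        for (a_s, a_e, b_s, b_e) in merged:
            if min(a_e - a_s, b_e - b_s) < min_len:
                continue
            matches = lcs_matches(a[a_s:a_e], bs[b_s:b_e])
            identity = matches / max(a_e - a_s, b_e - b_s)
            if identity < min_identity:
                # X-drop endpoints can overshoot a short element into random
                # flank; trim back to the maximal-identity sub-span
                a_s, a_e, b_s, b_e, matches, identity = _trim_island(
                    a, bs, a_s, a_e, b_s, b_e, min_len)
            if identity < min_identity:
                continue
            if strand == "+":
                isl = ConservedIsland(a_s, a_e, b_s, b_e, matches, identity, "+")
            else:
                isl = ConservedIsland(a_s, a_e, len(b) - b_e, len(b) - b_s,
                                      matches, identity, "-")
            islands.append(isl)
    islands.sort(key=lambda x: (x.a_start, x.a_end, x.strand))
    return islands


def _trim_island(a: str, bs: str, a_s: int, a_e: int, b_s: int, b_e: int,
                 min_len: int, max_trim: int = 16
                 ) -> tuple[int, int, int, int, int, float]:
    """Trim island ends (in lockstep on both sequences) to the sub-span of
    maximal LCS identity, keeping both spans >= min_len."""
    best = (a_s, a_e, b_s, b_e, lcs_matches(a[a_s:a_e], bs[b_s:b_e]))
    best_id = best[4] / max(a_e - a_s, b_e - b_s)
    span = min(a_e - a_s, b_e - b_s)
    lmax = min(max_trim, span - min_len)
    for left in range(0, max(0, lmax) + 1):
        rmax = min(max_trim, span - min_len - left)
        for right in range(0, max(0, rmax) + 1):
            if left == 0 and right == 0:
                continue
            na_s, na_e = a_s + left, a_e - right
            nb_s, nb_e = b_s + left, b_e - right
            m = lcs_matches(a[na_s:na_e], bs[nb_s:nb_e])
            ident = m / max(na_e - na_s, nb_e - nb_s)
            if ident > best_id:
                best = (na_s, na_e, nb_s, nb_e, m)
                best_id = ident
    a_s, a_e, b_s, b_e, matches = best
    return a_s, a_e, b_s, b_e, matches, best_id


def _strand_islands(a8: np.ndarray, b8: np.ndarray, k: int, xdrop: float
                    ) -> list[tuple[int, int, int, int]]:
    """Raw extended seed islands for one orientation of b, deduplicated per
    diagonal."""
    index: dict[bytes, list[int]] = defaultdict(list)
    av = a8.tobytes()
    for i in range(len(a8) - k + 1):
        kmer = av[i:i + k]
        if 4 in kmer:
            continue
        index[kmer].append(i)
    bv = b8.tobytes()
    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)
    out: list[tuple[int, int, int, int]] = []
    for j in range(len(b8) - k + 1):
        kmer = bv[j:j + k]
        if 4 in kmer:
            continue
        for i in index.get(kmer, ()):
            diag = i - j
            if any(s <= i and i + k <= e for s, e in covered[diag]):
                continue
            left, right = _xdrop_extend(a8, b8, i, j, k, xdrop)
            a_s, a_e = i - left, i + k + right
            out.append((a_s, a_e, j - left, j + k + right))
            covered[diag].append((a_s, a_e))
    return out


def _merge_diagonal(raw: list[tuple[int, int, int, int]], window: int
                    ) -> list[tuple[int, int, int, int]]:
    """Merge islands whose diagonals differ by at most ``window`` and whose
    a-spans overlap or are separated by at most ``window`` bp."""
    if not raw:
        return []
    items = sorted(raw, key=lambda t: (t[0], t[1]))
    clusters: list[list[int]] = []  # [a_s, a_e, b_s, b_e]
    for a_s, a_e, b_s, b_e in items:
        diag = a_s - b_s
        placed = False
        for cl in clusters:
            cdiag = cl[0] - cl[2]
            if abs(diag - cdiag) <= window and a_s <= cl[1] + window and a_e >= cl[0] - window:
                cl[0] = min(cl[0], a_s)
                cl[1] = max(cl[1], a_e)
                cl[2] = min(cl[2], b_s)
                cl[3] = max(cl[3], b_e)
                placed = True
                break
        if not placed:
            clusters.append([a_s, a_e, b_s, b_e])
    return [tuple(cl) for cl in clusters]


def motif_identity(a: str, b: str) -> tuple[int, float]:
    """Match count and identity of two short motifs: LCS matches and
    matches / min(length)."""
    return lcs_matches(a, b), pairwise_identity(a, b, mode="lcs_min_len")


def scan_motif(seq: str, consensus: str, max_mm: int = 0) -> list[MotifMatch]:
    """Hamming-scan both strands of ``seq`` against an IUPAC consensus.

    Matches with at most ``max_mm`` mismatching positions are reported;
    minus-strand matches are reported at their top-strand coordinates.
    """
    if len(consensus) < 8:
        raise ValueError("consensus must be >= 8 nt")
    s8 = encode(seq)
    L, w = len(s8), len(consensus)
    if L < w:
        return []
    hits: list[MotifMatch] = []
    win = np.lib.stride_tricks.sliding_window_view(s8, w)
    for strand, pattern in (("+", consensus), ("-", revcomp(consensus))):
        allowed = iupac_allowed_matrix(pattern)
        okmat = allowed[np.arange(w)[None, :], win]
        mm = w - okmat.sum(axis=1)
        for pos in np.nonzero(mm <= max_mm)[0]:
            hits.append(MotifMatch(int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
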