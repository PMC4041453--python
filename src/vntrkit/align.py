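"""Pairwise alignment and identity machinery.

Global affine-gap alignment (Needleman–Wunsch with Gotoh states), longest
common subsequence match counting, identity conventions, and column-majority
consensus.  The aligner supports an optional band: kb-scale repeat-unit pairs
that differ only by substitutions sit close to the main diagonal, so a modest
band (default 200 columns in callers) gives the full-matrix optimum at a
fraction of the cost.

Identity conventions
--------------------
Two conventions are exposed because short-motif comparisons and unit-level
comparisons are conventionally reported differently:

``lcs_min_len``
    matches / min(len(a), len(b)), with matches = LCS length, i.e. the maximum
    number of identical aligned nucleotides over all possible alignments.
    This is the convention behind statements like "22 of 24 nucleotides".
``alignment_columns``
    matches / total columns of the optimal affine-gap global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode

NEG = -1.0e18

_M, _X, _Y = 0, 1, 2  # states: diagonal, gap-in-b (up), gap-in-a (left)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties.

    A gap of length g costs ``gap_open + g * gap_extend`` (both are negative
    numbers; the opening penalty is charged once per gap run).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class Alignment:
    """A global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    gaps: int
    score: float

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    def identity(self) -> float:
        """matches / alignment columns."""
        return self.matches / self.columns


def global_align(a: str, b: str, scheme: ScoringScheme | None = None,
                 band: int | None = None) -> Alignment:
    """Optimal affine-gap global alignment of ``a`` and ``b``.

    Parameters
    ----------
    band:
        Half-width of the diagonal band explored, or None for the full matrix.
        The band is widened automatically to cover the length difference, so
        the corner cells are always reachable.

    Tie-breaking is deterministic: at equal score the traceback prefers the
    diagonal move, then the up move (gap in ``b``), then the left move.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")

    n, m = len(a), len(b)
    w = max(n, m) if band is None else int(band)
    w = max(w, abs(n - m) + 1)
    W = 2 * w + 1

    a8 = encode(a)
    # b padded with sentinel code 9 at both ends so out-of-range j never matches
    b8pad = np.full(m + 2, 9, dtype=np.uint8)
    b8pad[1:m + 1] = encode(b)

    mat, mis = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    oe = go + ge

    ptrM = np.zeros((n + 1, W), dtype=np.int8)
    ptrX = np.zeros((n + 1, W), dtype=np.int8)
    ptrY = np.zeros((n + 1, W), dtype=np.int8)

    offs = np.arange(W)

    # row 0: j = -w + o
    j0 = offs - w
    prevM = np.full(W, NEG)
    prevX = np.full(W, NEG)
    prevY = np.full(W, NEG)
    prevM[w] = 0.0
    row0 = (j0 >= 1) & (j0 <= m)
    prevY[row0] = go + ge * j0[row0]
    ptrY[0, row0] = _Y
    if w + 1 < W and 1 <= m:
        ptrY[0, w + 1] = _M  # the first left move exits at the origin

    for i in range(1, n + 1):
        jv = i - w + offs                       # absolute j for this row
        valid = (jv >= 0) & (jv <= m)
        jc = np.clip(jv, 0, m + 1)

        # --- M: diagonal from (i-1, j-1), same band index
        bestPrev = np.maximum(np.maximum(prevM, prevX), prevY)
        src = np.where(prevM >= bestPrev, _M,
                       np.where(prevX >= bestPrev, _X, _Y)).astype(np.int8)
        sub = np.where(b8pad[jc] == a8[i - 1], mat, mis)
        curM = bestPrev + sub
        okM = valid & (jv >= 1)
        curM[~okM] = NEG
        ptrM[i] = src

        # --- X: up from (i-1, j) = previous row band index o+1
        pM = np.concatenate((prevM[1:], [NEG]))
        pX = np.concatenate((prevX[1:], [NEG]))
        pY = np.concatenate((prevY[1:], [NEG]))
        candM, candX, candY = pM + oe, pX + ge, pY + oe
        curX = np.maximum(np.maximum(candM, candX), candY)
        ptrX[i] = np.where(candM >= curX, _M,
                           np.where(candX >= curX, _X, _Y)).astype(np.int8)
        curX[~valid] = NEG

        # --- Y: left within the row, via prefix scan over gap-run starts
        Z = np.maximum(curM, curX)
        C = np.where(valid, Z - jv * ge, NEG)
        R = np.maximum.accumulate(C)
        curY = np.full(W, NEG)
        curY[1:] = go + jv[1:] * ge + R[:-1]
        okY = valid & (jv >= 1)
        curY[~okY] = NEG
        # pointer: prefer closing the run into M, then X, else extend Y
        fromM = np.zeros(W, dtype=bool)
        fromX = np.zeros(W, dtype=bool)
        fromM[1:] = curY[1:] == curM[:-1] + oe
        fromX[1:] = curY[1:] == curX[:-1] + oe
        ptrY[i] = np.where(fromM, _M, np.where(fromX, _X, _Y)).astype(np.int8)

        prevM, prevX, prevY = curM, curX, curY

    o_end = m - (n - w)
    finals = (prevM[o_end], prevX[o_end], prevY[o_end])
    best = max(finals)
    state = _M if finals[_M] >= best else (_X if finals[_X] >= best else _Y)

    # traceback
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    matches = mismatches = gaps = 0
    while i > 0 or j > 0:
        o = j - (i - w)
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            state = int(ptrM[i, o])
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            gaps += 1
            state = int(ptrX[i, o])
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            gaps += 1
            state = int(ptrY[i, o])
            j -= 1

    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     matches, mismatches, gaps, float(best))


def lcs_matches(a: str, b: str) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``.

    This equals the maximum achievable number of identical aligned
    nucleotides over all possible (gapped) alignments of the two strings.
    """
    if not a or not b:
        return 0
    a8, b8 = encode(a), encode(b)
    prev = np.zeros(len(b8) + 1, dtype=np.int32)
    for i in range(len(a8)):
        eq = (b8 == a8[i]) & (a8[i] < 4)  # N never matches
        cand = np.maximum(prev[1:], np.where(eq, prev[:-1] + 1, 0))
        prev = np.concatenate(([0], np.maximum.accumulate(cand)))
    return int(prev[-1])


def pairwise_identity(a: str, b: str, mode: str = "lcs_min_len",
                      scheme: ScoringScheme | None = None,
                      band: int | None = None) -> float:
    """Fractional identity between two sequences under a stated convention.

    ``lcs_min_len``: LCS matches / min(len).  ``alignment_columns``:
    matches / columns of the optimal global alignment.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if mode == "lcs_min_len":
        return lcs_matches(a, b) / min(len(a), len(b))
    if mode == "alignment_columns":
        aln = global_align(a, b, scheme=scheme, band=band)
        return aln.matches / aln.columns
    raise ValueError(f"unknown identity mode: {mode!r}")


def percent(fraction: float, decimals: int = 0) -> float:
    """Report a fraction as a percentage, rounded half-up."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(fraction * 100).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def consensus(units: list[str]) -> str:
    """Column-wise majority consensus of equal-length sequences.

    Ties are broken alphabetically (A < C < G < T).  Sequences of unequal
    length are rejected: build a gapped consensus with an aligner first.
    """
    if len(units) < 2:
        raise ValueError("consensus requires at least 2 sequences")
    L = len(units[0])
    if any(len(u) != L for u in units):
        raise ValueError(
            "consensus requires equal-length sequences; align them first "
            "(alignment-based consensus is out of scope here)")
    mat = np.vstack([encode(u) for u in units])
    counts = np.zeros((4, L), dtype=np.int32)
    for c in range(4):
        counts[c] = (mat == c).sum(axis=0)
    best = counts.argmax(axis=0)  # argmax returns the first (alphabetical) max
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[best].tobytes().decode("ascii")


def identity_matrix(units: list[str], mode: str = "alignment_columns",
                    scheme: ScoringScheme | None = None,
                    band: int | None = 200) -> np.ndarray:
    """Symmetric pairwise identity matrix over a list of sequences."""
    n = len(units)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(
                units[i], units[j], mode=mode, scheme=scheme, band=band)
    return mat
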