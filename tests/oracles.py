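"""Independent brute-force oracles used to validate the DP/scan implementations.

Each oracle is deliberately naive (enumeration or direct per-window
evaluation) and shares no code with the implementation it checks.
"""

from functools import lru_cache


def brute_force_global_score(a: str, b: str, match=1.0, mismatch=-1.0,
                             gap_open=-3.0, gap_extend=-1.0) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    An alignment is a sequence of moves D (diagonal), U (consume a), L
    (consume b); each maximal U- or L-run of length g costs
    gap_open + g*gap_extend.
    """
    best = [float("-inf")]

    def score(moves) -> float:
        x = y = 0
        s = 0.0
        run = None
        for mv in moves:
            if mv == "D":
                s += match if a[x] == b[y] else mismatch
                x += 1
                y += 1
                run = None
            else:
                s += (gap_open if run != mv else 0.0) + gap_extend
                if mv == "U":
                    x += 1
                else:
                    y += 1
                run = mv
        return s

    def rec(i, j, moves):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(moves))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, moves + "D")
        if i < len(a):
            rec(i + 1, j, moves + "U")
        if j < len(b):
            rec(i, j + 1, moves + "L")

    rec(0, 0, "")
    return best[0]


def brute_force_lcs(a: str, b: str) -> int:
    """LCS length by plain recursion with memoization."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def brute_force_offset_spectrum(seq: str, k: int, min_period: int,
                                max_period: int) -> dict[int, int]:
    """All-pairs k-mer comparison by direct string slicing."""
    counts: dict[int, int] = {}
    n = len(seq)
    for i in range(n - k + 1):
        ki = seq[i:i + k]
        if "N" in ki:
            continue
        for j in range(i + min_period, min(i + max_period, n - k) + 1):
            if "N" in seq[j:j + k]:
                continue
            if ki == seq[j:j + k]:
                d = j - i
                counts[d] = counts.get(d, 0) + 1
    return counts


def brute_force_cgi(seq: str, min_len=200, min_gc=0.5, min_oe=0.6,
                    window=200, max_n_fraction=0.10) -> list[tuple[int, int]]:
    """Per-window CGI evaluation by direct counting, then interval union."""
    passing = []
    for i in range(len(seq) - window + 1):
        w = seq[i:i + window]
        n_amb = w.count("N")
        if n_amb > max_n_fraction * window:
            continue
        acgt = window - n_amb
        if acgt == 0:
            continue
        gc = (w.count("G") + w.count("C")) / acgt
        cg = w.count("CG")
        c, g = w.count("C"), w.count("G")
        oe = cg * window / (c * g) if c * g else 0.0
        if gc >= min_gc and oe >= min_oe:
            passing.append(i)
    merged: list[list[int]] = []
    for i in passing:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], i + window)
        else:
            merged.append([i, i + window])
    return [(s, e) for s, e in merged if e - s >= min_len]


def brute_force_union_length(intervals, clip=None) -> int:
    """Covered length by marking individual positions in a set."""
    covered: set[int] = set()
    for s, e in intervals:
        covered.update(range(s, e))
    if clip is not None:
        covered = {p for p in covered if clip[0] <= p < clip[1]}
    return len(covered)
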