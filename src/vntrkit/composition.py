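"""Base composition, CpG statistics, CpG-island calling, repeat-class enrichment.

CpG islands are called with the classical Gardiner-Garden & Frommer criteria:
200-bp windows with GC >= 50% and CpG observed/expected >= 0.6, slid at
single-base resolution and merged into maximal intervals.  Repeat-class
enrichment is bp-coverage based: the union length of class intervals inside a
region, as a fraction of the region, against a background fraction that may
come from intervals or from a published constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode


class UndefinedStatistic(ValueError):
    """Raised when a statistic is undefined for the input (e.g. all-N)."""


@dataclass
class CompositionReport:
    gc_fraction: float | None = None
    cpg_count: int = 0
    cpg_obs_exp: float = 0.0
    cgi_intervals: list[tuple[int, int]] = field(default_factory=list)
    class_coverage: dict[str, float] = field(default_factory=dict)
    fold_enrichment: dict[str, float | None] = field(default_factory=dict)


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N bases are excluded entirely."""
    codes = encode(seq)
    acgt = int((codes < 4).sum())
    if acgt == 0:
        raise UndefinedStatistic("GC fraction undefined: no A/C/G/T bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / acgt


def cpg_stats(seq: str) -> tuple[int, float]:
    """CpG dinucleotide count and observed/expected ratio.

    obs/exp = count * N / (#C * #G) with N = sequence length; defined as 0
    when #C * #G == 0.
    """
    codes = encode(seq)
    n_c = int((codes == 1).sum())
    n_g = int((codes == 2).sum())
    count = int(((codes[:-1] == 1) & (codes[1:] == 2)).sum()) if len(codes) > 1 else 0
    if n_c * n_g == 0:
        return count, 0.0
    return count, count * len(seq) / (n_c * n_g)


def call_cgi(seq: str, min_len: int = 200, min_gc: float = 0.5,
             min_oe: float = 0.6, window: int = 200,
             max_n_fraction: float = 0.10) -> list[tuple[int, int]]:
    """CpG-island intervals under sliding-window Gardiner-Garden–Frommer rules.

    Every ``window``-bp window (step 1) is tested for GC >= min_gc and CpG
    obs/exp >= min_oe; passing windows are merged into maximal intervals and
    intervals shorter than ``min_len`` are discarded.  Windows with more than
    ``max_n_fraction`` ambiguous bases are skipped.
    """
    if min_len <= 0 or window <= 0:
        raise ValueError("thresholds must be positive")
    L = len(seq)
    if L < window:
        return []
    codes = encode(seq)
    is_c = (codes == 1).astype(np.int64)
    is_g = (codes == 2).astype(np.int64)
    is_n = (codes >= 4).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)

    def wsum(x: np.ndarray, w: int) -> np.ndarray:
        c = np.concatenate(([0], np.cumsum(x)))
        return c[w:] - c[:-w]

    n_w = L - window + 1
    c_w = wsum(is_c, window)[:n_w]
    g_w = wsum(is_g, window)[:n_w]
    n_amb = wsum(is_n, window)[:n_w]
    cg_w = wsum(is_cg, window - 1)[:n_w] if window > 1 else np.zeros(n_w, dtype=np.int64)
    acgt = window - n_amb
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(acgt > 0, (c_w + g_w) / np.maximum(acgt, 1), 0.0)
        oe = np.where(c_w * g_w > 0, cg_w * window / np.maximum(c_w * g_w, 1), 0.0)
    passing = (gc >= min_gc) & (oe >= min_oe) & (n_amb <= max_n_fraction * window)

    intervals: list[tuple[int, int]] = []
    idx = np.nonzero(passing)[0]
    if len(idx) == 0:
        return intervals
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i <= prev + window:  # windows overlap or abut: same island
            prev = i
        else:
            intervals.append((start, prev + window))
            start = prev = i
    intervals.append((start, prev + window))
    return [(s, e) for s, e in intervals if e - s >= min_len]


def union_length(intervals: list[tuple[int, int]],
                 clip: tuple[int, int] | None = None) -> int:
    """Total covered length of a set of half-open intervals, optionally
    clipped to a region.  Order-independent and idempotent."""
    if clip is not None:
        lo, hi = clip
        intervals = [(max(s, lo), min(e, hi)) for s, e in intervals]
    intervals = sorted((s, e) for s, e in intervals if e > s)
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in intervals:
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def class_enrichment(region: tuple[int, int],
                     annotations: list[tuple[int, int, str]],
                     background: tuple[int, int] | dict[str, float] | None = None
                     ) -> CompositionReport:
    """Per-class bp coverage of a region and fold enrichment vs background.

    ``annotations`` are (start, end, class-label) intervals.  ``background``
    is either an enclosing interval (class fractions are computed from the
    same annotations over it) or a mapping class-label -> fraction (e.g. a
    published chromosome average).  Fold enrichment is None (undefined) when
    the background fraction is zero.
    """
    r_lo, r_hi = region
    if r_hi <= r_lo:
        raise ValueError("empty region")
    labels = sorted({lab for _, _, lab in annotations})
    report = CompositionReport()
    for lab in labels:
        ivs = [(s, e) for s, e, l in annotations if l == lab]
        frac = union_length(ivs, clip=region) / (r_hi - r_lo)
        report.class_coverage[lab] = frac
        bg: float | None = None
        if isinstance(background, dict):
            bg = background.get(lab)
        elif background is not None:
            b_lo, b_hi = background
            if not (b_lo <= r_lo and r_hi <= b_hi):
                raise ValueError("region must lie within the background interval")
            bg = union_length(ivs, clip=background) / (b_hi - b_lo)
        if bg is None:
            report.fold_enrichment[lab] = None
        elif bg == 0:
            report.fold_enrichment[lab] = None
        else:
            report.fold_enrichment[lab] = frac / bg
    return report


def composition_report(seq: str, annotations=None, region=None,
                       background=None, **cgi_kwargs) -> CompositionReport:
    """Full composition report for a sequence: GC, CpG stats, CGI intervals,
    and (when annotations are given) class coverage/enrichment."""
    report = CompositionReport()
    try:
        report.gc_fraction = gc_fraction(seq)
    except UndefinedStatistic:
        report.gc_fraction = None
    report.cpg_count, report.cpg_obs_exp = cpg_stats(seq)
    report.cgi_intervals = call_cgi(seq, **cgi_kwargs)
    if annotations:
        reg = region if region is not None else (0, len(seq))
        enr = class_enrichment(reg, annotations, background)
        report.class_coverage = enr.class_coverage
        report.fold_enrichment = enr.fold_enrichment
    return report
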