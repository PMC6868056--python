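"""Independent brute-force oracles used across the test suite.

Everything here works on explicit per-base boolean/integer arrays over a toy
chromosome, deliberately avoiding the interval arithmetic it is used to
check.
"""

from __future__ import annotations

import numpy as np

from dhskit.intervals import GenomicInterval, IntervalSet


def coverage(intervals, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base coverage of one chromosome."""
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start:iv.end] = True
    return cov


def union_bases(interval_sets, chroms: dict) -> int:
    """Per-base union size of several interval sets over a toy genome."""
    total = 0
    for chrom, length in chroms.items():
        cov = np.zeros(length, dtype=bool)
        for s in interval_sets:
            cov |= coverage(s, chrom, length)
        total += int(cov.sum())
    return total


def intervals_from_coverage(cov: np.ndarray, chrom: str) -> IntervalSet:
    """Maximal runs of True bases as a normalized interval set."""
    padded = np.concatenate(([False], cov, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return IntervalSet([GenomicInterval(chrom, int(s), int(e))
                        for s, e in zip(starts, ends)])


def random_interval_set(rng: np.random.Generator, chrom: str = "chr1",
                        length: int = 10_000, n: int = 100,
                        max_width: int = 200) -> IntervalSet:
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return IntervalSet([GenomicInterval(chrom, int(s), int(s + w))
                        for s, w in zip(starts, widths)])


def tally_oracle(track, dhss) -> np.ndarray:
    """Naive per-base summation of cuts within each DHS."""
    out = np.zeros(len(dhss), dtype=np.int64)
    for i, iv in enumerate(dhss):
        pos, cnt = track.chrom_positions(iv.chrom)
        for p, c in zip(pos, cnt):
            if iv.start <= p < iv.end:
                out[i] += c
    return out


def cone_oracle(count_a: float, count_b: float, slope_margin: float = 0.21,
                intercept: float = 0.9, min_cleavage: float = 50) -> str:
    """Direct evaluation of the two line inequalities.

    Dynamic means the point is strictly on the same side of BOTH lines
    (i.e. outside the band between them) and passes the raw-cut gate.
    """
    import math

    if max(count_a, count_b) <= min_cleavage:
        return "static"
    x = math.log10(count_a) if count_a > 0 else -math.inf
    y = math.log10(count_b) if count_b > 0 else -math.inf
    l1 = (1 - slope_margin) * x + intercept
    l2 = (1 + slope_margin) * x - intercept
    if y > l1 and y > l2:
        return "activated"
    if y < l1 and y < l2:
        return "deactivated"
    return "static"


def hypergeom_upper_tail_exact(universe_n: int, set1_n: int, set2_n: int,
                               observed: int):
    """Exact upper-tail hypergeometric probability by rational counting.

    Sums C(n1, k) * C(N - n1, n2 - k) / C(N, n2) over k >= observed with
    integer arithmetic (fractions), independent of any statistics library.
    """
    from fractions import Fraction
    from math import comb

    total = comb(universe_n, set2_n)
    hi = min(set1_n, set2_n)
    acc = sum(comb(set1_n, k) * comb(universe_n - set1_n, set2_n - k)
              for k in range(observed, hi + 1))
    return Fraction(acc, total)
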