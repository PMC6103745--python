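"""Independent brute-force oracles used only by the test suite."""

import math


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(k: int, total: int, marked: int, drawn: int) -> float:
    """P(X = k) drawing ``drawn`` without replacement from ``total`` with ``marked`` marked."""
    if k < max(0, drawn + marked - total) or k > min(marked, drawn):
        return 0.0
    return math.exp(
        _log_binom(marked, k) + _log_binom(total - marked, drawn - k) - _log_binom(total, drawn)
    )


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, total, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        pk = hypergeom_pmf(k, total, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(1.0, p)


def fisher_one_sided_enrichment(overlap: int, total: int, size_a: int, size_b: int) -> float:
    """P(X >= overlap) for |A ∩ B| with both sets drawn from a universe."""
    p = 0.0
    for k in range(overlap, min(size_a, size_b) + 1):
        p += hypergeom_pmf(k, total, size_a, size_b)
    return min(1.0, p)


def count_overlap_quadratic(peaks_a, peaks_b, stranded: bool = False) -> int:
    """All-pairs overlap counter (half-open, each A counted once)."""
    count = 0
    for iv_a in peaks_a.intervals:
        for iv_b in peaks_b.intervals:
            if iv_a.chrom != iv_b.chrom:
                continue
            if stranded and iv_a.strand != iv_b.strand:
                continue
            if iv_a.start < iv_b.end and iv_b.start < iv_a.end:
                count += 1
                break
    return count
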