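"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions, without reusing the
package's code paths: ranks by pairwise counting, tail probabilities by
exact rational arithmetic, null distributions by full enumeration.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def average_ranks(values) -> list[float]:
    """1-based midranks computed by O(n^2) pairwise comparison."""
    ranks = []
    for x in values:
        less = sum(1 for y in values if y < x)
        equal = sum(1 for y in values if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def tmm_factors_bruteforce(counts, trim_m=0.30, trim_a=0.05) -> dict[str, float]:
    """Trimmed weighted mean of M-values, sample by sample, pure Python.

    ``counts``: mapping sample -> list of counts (same gene order).
    Reference = sample whose 75th-percentile count fraction is closest to
    the across-sample mean (same convention as the implementation).
    """
    samples = list(counts)
    libs = {s: float(sum(counts[s])) for s in samples}
    f75 = {s: float(np.quantile([c / libs[s] for c in counts[s]], 0.75))
           for s in samples}
    mean75 = sum(f75.values()) / len(samples)
    ref = min(samples, key=lambda s: (abs(f75[s] - mean75), samples.index(s)))

    log_factors = {}
    for s in samples:
        pairs = [(yk, yr) for yk, yr in zip(counts[s], counts[ref])
                 if yk > 0 and yr > 0]
        ms, as_, ws = [], [], []
        for yk, yr in pairs:
            pk = yk / libs[s]
            pr = yr / libs[ref]
            ms.append(math.log2(pk / pr))
            as_.append(0.5 * math.log2(pk * pr))
            var = (libs[s] - yk) / (libs[s] * yk) + (libs[ref] - yr) / (libs[ref] * yr)
            ws.append(1.0 / var)
        n = len(ms)
        rm = average_ranks(ms)
        ra = average_ranks(as_)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for m, a, w, r1, r2 in zip(ms, as_, ws, rm, ra):
            if lo_m <= r1 <= hi_m and lo_a <= r2 <= hi_a:
                num += w * m
                den += w
        log_factors[s] = num / den if den > 0 else 0.0

    shift = sum(log_factors.values()) / len(samples)
    return {s: 2.0 ** (log_factors[s] - shift) for s in samples}


def ranksum_p_enumeration(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating every labeling."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = average_ranks(pooled)
    w_obs = sum(ranks[:n_a])
    mu = n_a * (len(pooled) + 1) / 2.0
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def hypergeom_upper_tail_exact(k: int, n_universe: int, n_term: int,
                               n_selected: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    denom = math.comb(n_universe, n_selected)
    total = Fraction(0)
    for i in range(k, min(n_term, n_selected) + 1):
        total += Fraction(math.comb(n_term, i)
                          * math.comb(n_universe - n_term, n_selected - i), denom)
    return total


def interval_union_length(intervals) -> int:
    """Union length of 1-based inclusive intervals, by position scan."""
    covered: set[int] = set()
    for start, end in intervals:
        covered.update(range(start, end + 1))
    return len(covered)
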