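"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-base scans, exhaustive
enumerations, closed-form arithmetic — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def brute_force_positional_class(feat, coding, intergenic_label: str) -> str:
    """Per-base positional classification.

    Marks every base of the feature span against every coding transcript:
    any base inside an opposite-strand coding span -> antisense; else any
    feature-exon base inside a same-strand coding exon -> sense; else any
    base inside a same-strand coding span -> intronic; else intergenic.
    """
    span_bases = set(range(feat.start, feat.end + 1))
    exon_bases = set()
    for s, e in feat.exons:
        exon_bases.update(range(s, e + 1))
    anti = sense = intron = False
    for c in coding:
        if c.chrom != feat.chrom:
            continue
        c_span = set(range(c.start, c.end + 1))
        if not (span_bases & c_span):
            continue
        if c.strand != feat.strand:
            anti = True
            continue
        c_exons = set()
        for s, e in c.exons:
            c_exons.update(range(s, e + 1))
        if exon_bases & c_exons:
            sense = True
        else:
            intron = True
    if anti:
        return "antisense"
    if sense:
        return "sense"
    if intron:
        return "intronic"
    return intergenic_label


def brute_force_exon_length(feat) -> int:
    bases = set()
    for s, e in feat.exons:
        bases.update(range(s, e + 1))
    return len(bases)


def ks_statistic_bruteforce(a, b) -> float:
    """sup |ECDF_a - ECDF_b| evaluated at every sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def bh_stepup_bruteforce(p) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def fisher_tail_exact(k: int, a: int, b: int, n: int) -> float:
    """P(overlap >= k) for |A|=a, |B|=b drawn from a universe of n, by
    exact integer hypergeometric summation."""
    denom = math.comb(n, b)
    num = 0
    for kk in range(k, min(a, b) + 1):
        if b - kk > n - a:
            continue
        num += math.comb(a, kk) * math.comb(n - a, b - kk)
    return float(Fraction(num, denom))


def pearson_r_handformula(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x ** 2).sum() - sx ** 2) * math.sqrt(n * (y ** 2).sum() - sy ** 2)
    return num / den


def pearson_p_permutation(x, y) -> float:
    """Exact permutation p-value for |r| (all n! permutations of y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    r_obs = abs(pearson_r_handformula(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(pearson_r_handformula(x, perm)) >= r_obs - 1e-12:
            hits += 1
    return hits / total


def welch_t_handformula(a, b) -> tuple[float, float]:
    """Welch t statistic and degrees of freedom from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
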