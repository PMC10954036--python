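"""Independent reference implementations used to cross-check the package.

These deliberately take different algebraic/algorithmic routes than the
library code: numeric sums-of-squares ANOVA for the variance-component FST,
exhaustive pair counting for diversity and EHH, and hypergeometric
summation for the exact test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def wc_fst_anova(genotypes_by_pop: list[np.ndarray]) -> float:
    """Weir–Cockerham theta for one site via numeric nested-ANOVA mean squares.

    ``genotypes_by_pop``: per population, the 0/1/2 dosages of its genotyped
    diploids (missing already removed). Returns NaN when undefined.

    Allele copies x_ijk in {0,1} are decomposed as copies-within-individuals
    within populations; the moment equations
        E[MS_G] = s2_G
        E[MS_I] = s2_G + 2 s2_I
        E[MS_P] = s2_G + 2 s2_I + 2 n_c s2_P
    are solved numerically and theta = s2_P / (s2_P + s2_I + s2_G).
    """
    pops = [g for g in genotypes_by_pop]
    r = len(pops)
    n_i = np.array([len(g) for g in pops], dtype=float)
    if (n_i < 1).any():
        return np.nan
    # individual allele means (0, .5, 1) and population allele frequencies
    p_ij = [g / 2.0 for g in pops]
    p_i = np.array([p.mean() for p in p_ij])
    n_tot = n_i.sum()
    p_all = float(np.sum(n_i * p_i) / n_tot)
    if p_all in (0.0, 1.0):
        return np.nan

    ss_p = float(np.sum(2 * n_i * (p_i - p_all) ** 2))
    ss_i = float(sum(2 * ((p - p.mean()) ** 2).sum() for p in p_ij))
    ss_g = 0.0
    for g in pops:
        for dose in g:
            x = np.array([1, 1]) if dose == 2 else (np.array([0, 0]) if dose == 0 else np.array([0, 1]))
            ss_g += ((x - x.mean()) ** 2).sum()
    df_p = r - 1
    df_i = n_tot - r
    df_g = n_tot
    ms_p = ss_p / df_p
    ms_i = ss_i / df_i
    ms_g = ss_g / df_g
    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    s2_g = ms_g
    s2_i = (ms_i - s2_g) / 2.0
    s2_p = (ms_p - s2_g - 2 * s2_i) / (2 * n_c)
    denom = s2_p + s2_i + s2_g
    if denom == 0:
        return np.nan
    return s2_p / denom


def pi_pairwise(haplotype_alleles: np.ndarray) -> float:
    """Mean pairwise difference at one site over all haplotype pairs."""
    a = np.asarray(haplotype_alleles)
    n = a.size
    if n < 2:
        return np.nan
    diff = sum(1 for x, y in combinations(a, 2) if x != y)
    return diff / (n * (n - 1) / 2)


def ehh_pair_counting(alleles: np.ndarray, core: int, extension: int) -> float:
    """EHH over the closed span [core..extension] by exhaustive pair counting."""
    lo, hi = min(core, extension), max(core, extension)
    span = alleles[:, lo:hi + 1]
    n = span.shape[0]
    ident = sum(
        1 for i, j in combinations(range(n), 2) if np.array_equal(span[i], span[j])
    )
    return ident / (n * (n - 1) / 2)


def fisher_hypergeom_sum(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by hypergeometric summation (point-prob rule)."""
    t = np.asarray(table, dtype=int)
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def merge_gap_union(positions: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Region oracle: union of +-gap/2 intervals, clipped to member positions."""
    pos = np.sort(np.asarray(positions))
    if pos.size == 0:
        return []
    intervals = [(p - gap / 2, p + gap / 2, p) for p in pos]
    merged = []
    cur = [intervals[0]]
    for iv in intervals[1:]:
        if iv[0] <= cur[-1][1]:
            cur.append(iv)
        else:
            merged.append(cur)
            cur = [iv]
    merged.append(cur)
    return [(int(c[0][2]), int(c[-1][2])) for c in merged]
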