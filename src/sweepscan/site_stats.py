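"""Per-SNP two-population differentiation and nucleotide diversity.

FST is the Weir & Cockerham (1984) theta for two populations — the
variance-component (AMOVA-consistent) estimator a/(a+b+c) with sample-size
correction. Negative per-site estimates are retained by default so that the
downstream bootstrap null is not distorted; an optional clamp to zero exists
for display purposes.

Nucleotide diversity is the variant-site form: at a site with n non-missing
allele copies and alt frequency p,

    pi = n/(n-1) * (1 - p^2 - q^2)  =  2pq * n/(n-1),

which equals the mean pairwise difference over all C(n,2) haplotype pairs.
No per-bp normalisation by locus length is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .vcf_io import MISSING, PopulationMap

__all__ = ["SiteStatResult", "fst_per_site", "pi_variant_site"]


@dataclass
class SiteStatResult:
    """A per-site statistic track aligned to a VariantTable.

    ``values`` holds NaN at undefined sites; ``defined`` is the boolean mask;
    ``n_alleles`` gives non-missing allele-copy counts (populations × sites).
    """

    values: np.ndarray
    defined: np.ndarray
    n_alleles: np.ndarray


def _pop_counts(genotypes: np.ndarray, rows: np.ndarray):
    """Per-site (n diploids genotyped, alt-allele count, het count) for one population."""
    g = genotypes[rows]
    ok = g != MISSING
    n = ok.sum(axis=0)
    ac = np.where(ok, g, 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    return n.astype(np.float64), ac.astype(np.float64), het.astype(np.float64)


def fst_per_site(
    genotypes: np.ndarray,
    sample_ids: list[str],
    popmap: PopulationMap,
    pop_pair: tuple[str, str],
    clamp_negative: bool = False,
) -> SiteStatResult:
    """Weir–Cockerham theta per site between ``pop_pair``.

    A site is defined when both populations have >= 2 genotyped diploids and
    the site is polymorphic across the pair; otherwise NaN. Raises
    ``DataError`` if a population has < 2 genotyped samples at every site.
    """
    r = 2
    rows = [popmap.sample_indices(p, sample_ids) for p in pop_pair]
    stats = [_pop_counts(genotypes, rw) for rw in rows]
    n_i = np.stack([s[0] for s in stats])      # (2, S) diploid counts
    ac_i = np.stack([s[1] for s in stats])
    het_i = np.stack([s[2] for s in stats])

    for k, p in enumerate(pop_pair):
        if n_i[k].max(initial=0) < 2:
            raise DataError(f"population too small: {p!r} has <2 genotyped samples at every site")

    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = ac_i / (2 * n_i)
        h_i = het_i / n_i
        nbar = n_i.sum(axis=0) / r
        pbar = ac_i.sum(axis=0) / (2 * n_i.sum(axis=0))
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = het_i.sum(axis=0) / n_i.sum(axis=0)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = a / denom

    defined = (
        (n_i >= 2).all(axis=0)
        & (pbar > 0)
        & (pbar < 1)
        & np.isfinite(theta)
        & (denom != 0)
    )
    values = np.where(defined, theta, np.nan)
    if clamp_negative:
        values = np.where(defined & (values < 0), 0.0, values)
    return SiteStatResult(values=values, defined=defined, n_alleles=(2 * n_i))


def pi_variant_site(
    genotypes: np.ndarray,
    sample_ids: list[str],
    popmap: PopulationMap,
    population: str,
) -> SiteStatResult:
    """Variant-site nucleotide diversity for one population.

    Sites with fewer than 2 non-missing allele copies are undefined, not zero.
    Monomorphic sites within the population give pi = 0 (they stay in the
    track: the statistic is defined there, the site simply carries no
    within-population diversity).
    """
    rows = popmap.sample_indices(population, sample_ids)
    n_dip, ac, _ = _pop_counts(genotypes, rows)
    n = 2 * n_dip
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ac / n
        pi = (n / (n - 1)) * 2 * p * (1 - p)
    defined = n >= 2
    values = np.where(defined, pi, np.nan)
    return SiteStatResult(values=values, defined=defined, n_alleles=n[None, :])
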