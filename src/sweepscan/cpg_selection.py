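"""Selection on methylation substrate: CpG intactness and exact tests.

Methylated cytosines deaminate to thymine an order of magnitude faster than
unmethylated ones, so a methylated CpG is a mutable site: haplotypes either
retain the intact "CG" dinucleotide or carry a disrupted variant (typically
"TG"). Comparing intact-CpG counts between populations at designated sites
asks whether one population preserves the methylation substrate — a 2x2
(population x intact/disrupted) Fisher exact test per site.

The companion screen takes per-position mean methylation fractions from two
populations, reports their squared Pearson correlation, and flags positions
whose focal-population mean exceeds the reference by at least ``fold``
(default 4x), the candidates for substrate loss in the reference.

The exact test is the two-sided point-probability convention: with margins
fixed, p is the sum of hypergeometric point probabilities not exceeding that
of the observed table (relative tie tolerance 1e-12), enumerated over the
full feasible range of the top-left cell. One-sided alternatives are exposed
for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DataError, ValidationError

__all__ = [
    "CpGSiteTable",
    "cpg_intactness",
    "fisher_exact_2x2",
    "methylation_outliers",
]


@dataclass
class CpGSiteTable:
    """Per-site intact/disrupted CpG counts for two populations (DataFrame-backed)."""

    table: pd.DataFrame  # columns: site, pop, intact, disrupted

    def counts(self, site, populations) -> np.ndarray:
        """2x2 [[intact, disrupted] per population] matrix for one site."""
        rows = []
        for pop in populations:
            r = self.table[(self.table["site"] == site) & (self.table["pop"] == pop)]
            if len(r) != 1:
                raise DataError(f"site {site!r} has no counts for population {pop!r}")
            rows.append([int(r["intact"].iloc[0]), int(r["disrupted"].iloc[0])])
        return np.asarray(rows, dtype=np.int64)


def cpg_intactness(sequences: dict[str, str], cpg_positions, hap_population: dict[str, str]) -> CpGSiteTable:
    """Tabulate intact CpG dinucleotides per site and population.

    ``sequences`` maps haplotype id to its aligned locus sequence;
    ``cpg_positions`` are 1-based reference coordinates of the C of each CpG;
    ``hap_population`` maps haplotype id to population. A haplotype is intact
    at a site iff the dinucleotide at (pos, pos+1) is exactly "CG"; ambiguous
    bases (anything outside ACGT) drop the haplotype from that site's
    denominator.
    """
    records = []
    pops = list(dict.fromkeys(hap_population.values()))
    n_ambiguous = 0
    for pos in cpg_positions:
        pos = int(pos)
        tallies = {p: [0, 0] for p in pops}
        for hap_id, seq in sequences.items():
            if pos + 1 > len(seq):
                raise DataError(
                    f"CpG position {pos} beyond end of sequence {hap_id!r} (len {len(seq)})"
                )
            dinuc = seq[pos - 1:pos + 1].upper()
            if any(b not in "ACGT" for b in dinuc):
                n_ambiguous += 1
                continue
            pop = hap_population[hap_id]
            if dinuc == "CG":
                tallies[pop][0] += 1
            else:
                tallies[pop][1] += 1
        for p in pops:
            records.append(
                {"site": pos, "pop": p, "intact": tallies[p][0], "disrupted": tallies[p][1]}
            )
    if n_ambiguous:
        import logging

        logging.getLogger(__name__).info(
            "cpg_intactness: %d haplotype/site calls excluded as ambiguous", n_ambiguous
        )
    return CpGSiteTable(pd.DataFrame.from_records(records))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Exact p-value for a 2x2 contingency table by hypergeometric enumeration.

    Two-sided: sum of point probabilities <= the observed table's (within a
    1e-12 relative tie tolerance). "greater"/"less" are one-sided tails on
    the top-left cell. Any zero margin makes the observed table the only
    feasible one (p = 1).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise DataError("negative counts in contingency table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0:
        raise DataError("empty contingency table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    if alternative == "two-sided":
        mask = pmf <= p_obs * (1 + 1e-12)
        if mask.all():  # observed table is modal: the whole support is the tail
            return 1.0
        p = pmf[mask].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def cpg_fisher_tests(table: CpGSiteTable, populations, alternative: str = "two-sided") -> pd.DataFrame:
    """Fisher exact test per CpG site; returns site, per-pop intact fractions, p."""
    rows = []
    for site in table.table["site"].unique():
        m = table.counts(site, populations)
        rec = {"site": int(site), "p": fisher_exact_2x2(m, alternative)}
        for pop, (intact, disrupted) in zip(populations, m):
            denom = intact + disrupted
            rec[f"intact_frac_{pop}"] = intact / denom if denom else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def methylation_outliers(methylation: pd.DataFrame, focal: str, ref: str,
                         fold: float = 4.0) -> tuple[float, pd.DataFrame]:
    """Correlation and fold-change screen on per-position mean methylation.

    ``methylation`` needs columns ``position``, ``mean_<focal>``, ``mean_<ref>``.
    Returns (r^2 of focal vs reference means, table with a ``outlier`` column
    flagging positions where focal/ref >= fold; a reference mean of 0 with a
    positive focal mean is an outlier by convention).
    """
    fcol, rcol = f"mean_{focal}", f"mean_{ref}"
    for col in ("position", fcol, rcol):
        if col not in methylation.columns:
            raise ValidationError(f"methylation table lacks column {col!r}")
    x = methylation[fcol].to_numpy(dtype=float)
    y = methylation[rcol].to_numpy(dtype=float)
    if ((x < 0) | (x > 1) | (y < 0) | (y > 1)).any():
        raise DataError("methylation fractions must lie in [0, 1]")
    if x.size < 3:
        raise DataError("need >= 3 positions for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant methylation vector: r^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(y > 0, x / y, np.where(x > 0, np.inf, 1.0))
    out = methylation.copy()
    out["fold_ratio"] = ratio
    out["outlier"] = ratio >= fold
    return float(r**2), out
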