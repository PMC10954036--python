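"""Extended haplotype homozygosity (EHH), integrated EHH, and XP-EHH.

EHH at extension k from a core SNP is the probability that two randomly
chosen haplotypes are identical over the closed SNP span [core..k]:

    EHH_k = sum_h C(n_h, 2) / C(n, 2)

over identity groups h. It starts at the core site's haplotype homozygosity
and is non-increasing with distance. iHH is the trapezoidal integral of EHH
over physical distance, both directions summed; integration stops at the
first site whose EHH falls below the cutoff (that crossing segment is
included), and a core whose extension hits a scaffold end before decaying is
flagged boundary-censored rather than dropped.

XP-EHH compares the pooled (all-haplotype) EHH decay between a focal and a
reference population at the same core: raw = ln(iHH_focal / iHH_ref),
antisymmetric under population swap. Raw scores are standardised by their
genome-wide mean and SD to account for genome-wide differences in haplotype
length; outliers are cores whose |normalised| score reaches the empirical
(1 - top_fraction) quantile AND whose sign is positive (extended haplotypes
in the focal population). Short scaffolds carry too little room for LD decay,
so scaffolds must exceed a minimum length and SNP count before any score is
computed. No genetic-map or gap-scaling correction is applied between
distant SNPs: with reduced-representation data large gaps are the norm, and
the cross-population contrast absorbs shared gap structure.

Missing alleles are rejected throughout (pair identity is undefined under
missingness).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import DataError, ValidationError
from .vcf_io import HaplotypeSet, PopulationMap, ScaffoldInfo, VariantTable

__all__ = [
    "EHHProfile",
    "XPEHHScan",
    "HaplotypeSpectrum",
    "ehh_profile",
    "ihh",
    "xpehh_scan",
    "haplotype_spectrum",
    "bifurcation_tree",
]

EHH_CUTOFF_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# EHH profiles (readable reference path)

@dataclass
class EHHProfile:
    """EHH decay to one side of a core SNP.

    ``site_idx``/``distance_bp``/``ehh`` start at the core (distance 0,
    EHH = core-site homozygosity). Recording stops at the first value below
    the cutoff (that value is kept, so integration can include the crossing
    segment) or at the scaffold end.
    """

    core_idx: int
    direction: str  # "up" (increasing position) or "down"
    site_idx: np.ndarray
    distance_bp: np.ndarray
    ehh: np.ndarray
    truncation: str  # "cutoff" or "scaffold_end"
    cutoff: float


def _group_sizes(alleles: np.ndarray) -> np.ndarray:
    """Sizes of identity groups of rows of a (n x k) 0/1 matrix."""
    _, counts = np.unique(alleles, axis=0, return_counts=True)
    return counts


def _homozygosity(counts: np.ndarray, n: int) -> float:
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_profile(
    hapset: HaplotypeSet,
    core_idx: int,
    direction: str,
    cutoff: float = EHH_CUTOFF_DEFAULT,
    positions: np.ndarray | None = None,
) -> EHHProfile:
    """EHH decay from ``core_idx`` in one direction over a single scaffold.

    ``positions`` defaults to the site column index (unit spacing) when not
    given; pass real bp coordinates for physical distances.
    """
    hapset.require_complete("EHH")
    A = hapset.alleles
    n, S = A.shape
    if n < 2:
        raise DataError("EHH requires at least 2 haplotypes")
    if not 0 <= core_idx < S:
        raise ValidationError(f"core index {core_idx} out of range [0, {S})")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    pos = np.arange(S, dtype=np.int64) if positions is None else np.asarray(positions)

    step = 1 if direction == "up" else -1
    idx = [core_idx]
    ehh_vals = [_homozygosity(_group_sizes(A[:, [core_idx]]), n)]
    truncation = "scaffold_end"
    j = core_idx + step
    while 0 <= j < S and ehh_vals[-1] >= cutoff:
        lo, hi = (core_idx, j) if step == 1 else (j, core_idx)
        e = _homozygosity(_group_sizes(A[:, lo:hi + 1]), n)
        idx.append(j)
        ehh_vals.append(e)
        if e < cutoff:
            truncation = "cutoff"
            break
        j += step
    else:
        if ehh_vals[-1] < cutoff:
            truncation = "cutoff"
    site_idx = np.asarray(idx, dtype=np.int64)
    return EHHProfile(
        core_idx=core_idx,
        direction=direction,
        site_idx=site_idx,
        distance_bp=np.abs(pos[site_idx] - pos[core_idx]).astype(np.float64),
        ehh=np.asarray(ehh_vals, dtype=np.float64),
        truncation=truncation,
        cutoff=float(cutoff),
    )


def ihh(up: EHHProfile, down: EHHProfile) -> tuple[float, bool]:
    """Integrated EHH: trapezoid over physical distance, both sides summed.

    Returns (area in bp-equivalents, boundary-censored flag). The censored
    flag is set when either side ran into the scaffold end before the EHH
    decayed below the cutoff.
    """
    if up.core_idx != down.core_idx:
        raise ValidationError("profiles do not share a core")
    area = 0.0
    for prof in (up, down):
        if prof.distance_bp.size > 1:
            area += float(np.trapezoid(prof.ehh, prof.distance_bp))
    censored = up.truncation == "scaffold_end" or down.truncation == "scaffold_end"
    return area, censored


# ---------------------------------------------------------------------------
# Fast scan path (numba): iHH at every core of a scaffold

@njit(cache=True)
def _ihh_side(alleles, positions, core, step, cutoff):  # pragma: no cover - jitted
    n, S = alleles.shape
    pairs_tot = n * (n - 1) / 2.0
    labels = np.empty(n, dtype=np.int64)
    sizes = np.zeros(n + 1, dtype=np.int64)
    n0 = 0
    n1 = 0
    for i in range(n):
        if alleles[i, core] == 0:
            labels[i] = 0
            n0 += 1
        else:
            labels[i] = 1
            n1 += 1
    ehh_prev = (n0 * (n0 - 1) / 2.0 + n1 * (n1 - 1) / 2.0) / pairs_tot
    if ehh_prev < cutoff:
        return 0.0, False
    area = 0.0
    prev_pos = positions[core]
    remap = np.empty(2 * n + 2, dtype=np.int64)
    j = core + step
    while 0 <= j < S:
        remap[:] = -1
        ngroups = 0
        pair_sum = 0.0
        for i in range(n):
            key = labels[i] * 2 + alleles[i, j]
            g = remap[key]
            if g == -1:
                g = ngroups
                remap[key] = g
                sizes[g] = 0
                ngroups += 1
            labels[i] = -key - 10  # park: avoid clashing with fresh keys
            sizes[g] += 1
        # second pass to assign compacted labels
        for i in range(n):
            key = -labels[i] - 10
            labels[i] = remap[key]
        for g in range(ngroups):
            pair_sum += sizes[g] * (sizes[g] - 1) / 2.0
        ehh = pair_sum / pairs_tot
        d = positions[j] - prev_pos
        if d < 0:
            d = -d
        area += 0.5 * (ehh_prev + ehh) * d
        if ehh < cutoff:
            return area, False
        ehh_prev = ehh
        prev_pos = positions[j]
        j += step
    return area, True  # hit the scaffold end before decaying


@njit(cache=True)
def _ihh_scan_scaffold(alleles, positions, cutoff):  # pragma: no cover - jitted
    S = alleles.shape[1]
    out = np.empty(S, dtype=np.float64)
    censored = np.zeros(S, dtype=np.bool_)
    for c in range(S):
        a_up, c_up = _ihh_side(alleles, positions, c, 1, cutoff)
        a_dn, c_dn = _ihh_side(alleles, positions, c, -1, cutoff)
        out[c] = a_up + a_dn
        censored[c] = c_up or c_dn
    return out, censored


def ihh_scan(alleles: np.ndarray, positions: np.ndarray,
             cutoff: float = EHH_CUTOFF_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """iHH (both directions) at every core of one scaffold; returns (ihh, censored)."""
    A = np.ascontiguousarray(alleles, dtype=np.int8)
    if (A < 0).any():
        raise DataError("missing haplotype alleles are not supported by iHH scans")
    pos = np.ascontiguousarray(positions, dtype=np.int64)
    return _ihh_scan_scaffold(A, pos, float(cutoff))


# ---------------------------------------------------------------------------
# XP-EHH

@dataclass
class XPEHHScan:
    """XP-EHH scores at every usable core across filtered scaffolds."""

    scaffold: np.ndarray
    pos: np.ndarray
    ihh_focal: np.ndarray
    ihh_ref: np.ndarray
    raw: np.ndarray          # ln(iHH_focal / iHH_ref); NaN where undefined
    normalized: np.ndarray   # standardised over defined cores; NaN undefined
    defined: np.ndarray
    outlier: np.ndarray      # top-tail AND positive
    censored: np.ndarray
    threshold: float         # empirical |normalised| quantile applied
    filter_counts: dict = field(default_factory=dict)


def xpehh_scan(
    hap_focal: HaplotypeSet,
    hap_ref: HaplotypeSet,
    variants: VariantTable,
    scaffold_info: ScaffoldInfo,
    min_len: int = 300_000,
    min_snps: int = 20,
    top_fraction: float = 0.01,
    cutoff: float = EHH_CUTOFF_DEFAULT,
    drop_censored: bool = False,
) -> XPEHHScan:
    """Scan XP-EHH over all scaffolds longer than ``min_len`` with more than
    ``min_snps`` SNPs.

    Cores with iHH = 0 in either population are undefined and excluded from
    normalisation. ``drop_censored`` additionally excludes boundary-censored
    cores (strict mode); by default they are kept but flagged.
    """
    if hap_focal.alleles.shape[1] != len(variants) or hap_ref.alleles.shape[1] != len(variants):
        raise ValidationError("haplotype sets must cover the same sites as the variant table")
    hap_focal.require_complete("XP-EHH")
    hap_ref.require_complete("XP-EHH")

    kept, failed_len, failed_snps = [], 0, 0
    for name in variants.scaffolds:
        nsnps = int(variants.mask(name).sum())
        length = scaffold_info.get(name, 0)
        if length <= min_len:
            failed_len += 1
        elif nsnps <= min_snps:
            failed_snps += 1
        else:
            kept.append(name)
    counts = {
        "scaffolds_total": len(variants.scaffolds),
        "scaffolds_kept": len(kept),
        "failed_min_len": failed_len,
        "failed_min_snps": failed_snps,
    }
    if not kept:
        raise DataError(f"no scaffolds pass the XP-EHH filters: {counts}")

    scaf_l, pos_l, if_l, ir_l, cen_l = [], [], [], [], []
    for name in kept:
        m = variants.mask(name)
        pos = variants.pos[m]
        a_f = hap_focal.alleles[:, m]
        a_r = hap_ref.alleles[:, m]
        ihh_f, cen_f = ihh_scan(a_f, pos, cutoff)
        ihh_r, cen_r = ihh_scan(a_r, pos, cutoff)
        scaf_l.append(np.full(pos.size, name, dtype=object))
        pos_l.append(pos)
        if_l.append(ihh_f)
        ir_l.append(ihh_r)
        cen_l.append(cen_f | cen_r)
    scaffold = np.concatenate(scaf_l)
    pos = np.concatenate(pos_l)
    ihh_f = np.concatenate(if_l)
    ihh_r = np.concatenate(ir_l)
    censored = np.concatenate(cen_l)

    defined = (ihh_f > 0) & (ihh_r > 0)
    if drop_censored:
        defined &= ~censored
    raw = np.full(pos.size, np.nan)
    # log difference rather than log of the ratio: antisymmetry under
    # population swap is then exact in floating point
    raw[defined] = np.log(ihh_f[defined]) - np.log(ihh_r[defined])
    if not defined.any():
        raise DataError("no cores with positive iHH in both populations")
    mu = float(raw[defined].mean())
    sd = float(raw[defined].std())
    if sd == 0:
        raise DataError("degenerate XP-EHH track: all raw scores identical")
    normalized = np.full(pos.size, np.nan)
    normalized[defined] = (raw[defined] - mu) / sd
    threshold = float(np.quantile(np.abs(normalized[defined]), 1.0 - top_fraction))
    outlier = np.zeros(pos.size, dtype=bool)
    outlier[defined] = (np.abs(normalized[defined]) >= threshold) & (normalized[defined] > 0)
    return XPEHHScan(
        scaffold=scaffold, pos=pos, ihh_focal=ihh_f, ihh_ref=ihh_r,
        raw=raw, normalized=normalized, defined=defined, outlier=outlier,
        censored=censored, threshold=threshold, filter_counts=counts,
    )


# ---------------------------------------------------------------------------
# Haplotype frequency spectra and bifurcation trees

@dataclass
class HaplotypeSpectrum:
    """Exact-string haplotype frequencies over an interval, per population."""

    scaffold: str
    start: int
    end: int
    n_snps: int
    counts: dict[str, Counter]  # population -> haplotype string -> count

    def frequencies(self, population: str) -> dict[str, float]:
        c = self.counts[population]
        total = sum(c.values())
        return {h: k / total for h, k in c.items()}

    def dominant_frequency(self, population: str) -> float:
        c = self.counts[population]
        return max(c.values()) / sum(c.values())


def haplotype_spectrum(
    hapset: HaplotypeSet,
    popmap: PopulationMap,
    variants: VariantTable,
    scaffold: str,
    start: int,
    end: int,
) -> HaplotypeSpectrum:
    """Group haplotypes by exact string identity over the SNPs in [start, end]."""
    m = variants.mask(scaffold) & (variants.pos >= start) & (variants.pos <= end)
    if not m.any():
        raise DataError(f"interval {scaffold}:{start}-{end} contains no SNPs")
    sub = hapset.alleles[:, m]
    if (sub < 0).any():
        raise DataError("missing alleles inside the spectrum interval")
    counts: dict[str, Counter] = {}
    for pop in popmap.populations:
        rows = popmap.haplotype_rows(pop, hapset.sample_ids)
        strings = ["".join("01"[a] for a in sub[r]) for r in rows]
        counts[pop] = Counter(strings)
    return HaplotypeSpectrum(
        scaffold=scaffold, start=int(start), end=int(end),
        n_snps=int(m.sum()), counts=counts,
    )


def bifurcation_tree(
    hapset: HaplotypeSet,
    core_idx: int,
    direction: str,
    max_extent: int,
):
    """Nested allele-prefix tree from a core SNP (bifurcation diagram data).

    Each node holds the allele string accumulated from the core, the number
    of haplotypes carrying that prefix, and its children at the next SNP.
    Returns ``(root_children, truncated)``; ``truncated`` is set when
    ``max_extent`` SNPs were not available before the matrix edge. Leaf
    weights always sum to the haplotype count.
    """
    hapset.require_complete("bifurcation trees")
    A = hapset.alleles
    n, S = A.shape
    if not 0 <= core_idx < S:
        raise ValidationError(f"core index {core_idx} out of range [0, {S})")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    step = 1 if direction == "up" else -1
    sites = []
    j = core_idx
    for _ in range(max_extent + 1):
        if not 0 <= j < S:
            break
        sites.append(j)
        j += step
    truncated = len(sites) < max_extent + 1

    def build(rows: np.ndarray, depth: int, prefix: str) -> dict:
        node = {"prefix": prefix, "count": int(rows.size), "children": []}
        if depth < len(sites):
            col = A[rows, sites[depth]]
            for allele in (0, 1):
                sub = rows[col == allele]
                if sub.size:
                    node["children"].append(build(sub, depth + 1, prefix + str(allele)))
        return node

    root = build(np.arange(n), 0, "")
    return root["children"], truncated


def tree_to_lines(nodes, indent: int = 0) -> list[str]:
    """Serialise a bifurcation tree to indented text (one node per line)."""
    lines = []
    for node in nodes:
        lines.append("  " * indent + f"{node['prefix'] or '*'}\t{node['count']}")
        lines.extend(tree_to_lines(node["children"], indent + 1))
    return lines
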