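"""End-to-end scan orchestration: FST -> pi -> XP-EHH -> combined regions.

This is the library entry point the CLI, the analysis drivers and the
acceptance checks all share. Every stage is an importable function from the
sibling modules; this module only wires tracks together and collects the
results into one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernel_scan, site_stats
from .haplotype_stats import XPEHHScan, xpehh_scan
from .kernel_scan import BootstrapResult, SmoothedTrack, ZScoreTrack
from .outlier_integration import (
    OutlierRegion,
    call_regions,
    intersect_regions,
    intersect_tests,
    summarize_region,
)
from .vcf_io import HaplotypeSet, PopulationMap, ScaffoldInfo, VariantTable

__all__ = ["ScanParams", "ScanResult", "run_scan", "subset_haplotypes"]


@dataclass(frozen=True)
class ScanParams:
    """All scan thresholds in one place (defaults: the standard regime for this scan family)."""

    sigma_bp: float = 25_000.0     # Gaussian kernel scale
    z_cut: float = 5.0             # pi-ratio outliers: Z <= -z_cut
    alpha: float = 1e-5            # smoothed-FST outliers: bootstrap p < alpha
    B_max: int = 10_000_000        # bootstrap escalation ceiling
    ehh_cutoff: float = 0.05       # EHH integration cutoff
    min_scaffold_len: int = 300_000
    min_scaffold_snps: int = 20
    top_fraction: float = 0.01     # XP-EHH outlier tail
    merge_gap: int = 50_000        # region merging (2 sigma)
    clamp_negative_fst: bool = False
    seed: int = 0


@dataclass
class ScanResult:
    focal: str
    ref: str
    params: ScanParams
    fst: site_stats.SiteStatResult
    fst_track: SmoothedTrack
    fst_boot: BootstrapResult
    fst_flagged: np.ndarray
    pi_focal_track: SmoothedTrack
    pi_ref_track: SmoothedTrack
    zscore: ZScoreTrack
    xpehh: XPEHHScan
    regions: dict[str, list[OutlierRegion]] = field(default_factory=dict)
    combined: list[OutlierRegion] = field(default_factory=list)
    summaries: list[dict] = field(default_factory=list)

    def combined_pair(self, test_a: str, test_b: str) -> list[OutlierRegion]:
        """Two-test intersection (diagnostic view of partial support)."""
        return intersect_regions({t: self.regions[t] for t in (test_a, test_b)})

    def tracks_frame(self) -> pd.DataFrame:
        """Per-SNP table of every track (NaN where a test is undefined there)."""
        t = self.fst_track
        df = pd.DataFrame(
            {"scaffold": t.scaffold, "pos": t.pos, "fst_raw": t.raw,
             "fst_smoothed": t.smoothed, "fst_p": self.fst_boot.p,
             "fst_B": self.fst_boot.B_used, "fst_outlier": self.fst_flagged}
        )
        z = pd.DataFrame(
            {"scaffold": self.zscore.scaffold, "pos": self.zscore.pos,
             "pi_focal": self.pi_focal_track.smoothed,
             "pi_ref": self.pi_ref_track.smoothed,
             "log2_ratio": self.zscore.x, "z": self.zscore.z,
             "z_outlier": self.zscore.outlier}
        )
        x = pd.DataFrame(
            {"scaffold": self.xpehh.scaffold, "pos": self.xpehh.pos,
             "ihh_focal": self.xpehh.ihh_focal, "ihh_ref": self.xpehh.ihh_ref,
             "xpehh_raw": self.xpehh.raw, "xpehh_norm": self.xpehh.normalized,
             "xpehh_outlier": self.xpehh.outlier, "xpehh_censored": self.xpehh.censored}
        )
        out = df.merge(z, on=["scaffold", "pos"], how="outer")
        return out.merge(x, on=["scaffold", "pos"], how="outer").sort_values(
            ["scaffold", "pos"], kind="stable"
        ).reset_index(drop=True)


def subset_haplotypes(hapset: HaplotypeSet, popmap: PopulationMap, population: str) -> HaplotypeSet:
    """Haplotype set restricted to one population's samples."""
    samples = [s for s in hapset.sample_ids if popmap.assignments.get(s) == population]
    rows = hapset.rows_for_samples(samples)
    return HaplotypeSet(hapset.alleles[rows], samples)


def run_scan(
    variants: VariantTable,
    hapset: HaplotypeSet,
    genotypes: np.ndarray,
    popmap: PopulationMap,
    scaffold_info: ScaffoldInfo,
    focal: str,
    ref: str,
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Run the three outlier tests and combine their regions."""
    sample_ids = hapset.sample_ids
    pair = (focal, ref)

    # --- FST: per-site theta -> Gaussian smoothing -> bootstrap null
    fst = site_stats.fst_per_site(
        genotypes, sample_ids, popmap, pair, clamp_negative=params.clamp_negative_fst
    )
    d = fst.defined
    fst_track = kernel_scan.gaussian_smooth(
        variants.scaffold[d], variants.pos[d], fst.values[d], params.sigma_bp
    )
    fst_boot = kernel_scan.bootstrap_outlier_pvalues(
        fst_track, fst.values[d], B_max=params.B_max, alpha=params.alpha, seed=params.seed
    )
    fst_flagged = fst_boot.p < params.alpha

    # --- pi ratio: per-pop diversity on shared centers -> Z-score
    pi_f = site_stats.pi_variant_site(genotypes, sample_ids, popmap, focal)
    pi_r = site_stats.pi_variant_site(genotypes, sample_ids, popmap, ref)
    both = pi_f.defined & pi_r.defined
    pi_focal_track = kernel_scan.gaussian_smooth(
        variants.scaffold[both], variants.pos[both], pi_f.values[both], params.sigma_bp
    )
    pi_ref_track = kernel_scan.gaussian_smooth(
        variants.scaffold[both], variants.pos[both], pi_r.values[both], params.sigma_bp
    )
    zscore = kernel_scan.pi_ratio_zscore(pi_focal_track, pi_ref_track, z_cut=params.z_cut)

    # --- XP-EHH on filtered scaffolds
    xp = xpehh_scan(
        subset_haplotypes(hapset, popmap, focal),
        subset_haplotypes(hapset, popmap, ref),
        variants,
        scaffold_info,
        min_len=params.min_scaffold_len,
        min_snps=params.min_scaffold_snps,
        top_fraction=params.top_fraction,
        cutoff=params.ehh_cutoff,
    )

    regions = {
        "fst": call_regions(fst_track.scaffold, fst_track.pos, fst_flagged,
                            params.merge_gap, test="fst"),
        "pi": call_regions(zscore.scaffold, zscore.pos, zscore.outlier,
                           params.merge_gap, test="pi"),
        "xpehh": call_regions(xp.scaffold, xp.pos, xp.outlier,
                              params.merge_gap, test="xpehh"),
    }
    combined = intersect_tests(regions["fst"], regions["pi"], regions["xpehh"])

    result = ScanResult(
        focal=focal, ref=ref, params=params,
        fst=fst, fst_track=fst_track, fst_boot=fst_boot, fst_flagged=fst_flagged,
        pi_focal_track=pi_focal_track, pi_ref_track=pi_ref_track,
        zscore=zscore, xpehh=xp, regions=regions, combined=combined,
    )
    for region in combined:
        result.summaries.append(
            summarize_region(
                region,
                variants=variants,
                fst_track=fst_track,
                fst_point=np.where(fst.defined, fst.values, np.nan),
                zscore=zscore,
                xpehh=xp,
                pi_focal_track=pi_focal_track,
                hapset=hapset,
                popmap=popmap,
            )
        )
    return result
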