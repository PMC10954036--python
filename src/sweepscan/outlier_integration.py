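"""From per-test SNP flags to candidate sweep regions.

Flagged SNPs are merged into regions when they fall within ``merge_gap`` of
each other on the same scaffold (default 50 kb = 2 sigma of the smoothing
kernel, so regions are scale-consistent with the scan). Region bounds snap
to member SNP positions, matching how SNP-bounded intervals are reported.

The combined call intersects the three single-test region sets at the
interval level: a combined region is a maximal interval simultaneously
covered by at least one region from each test. Member SNPs that are
individually flagged by all three tests are additionally counted in the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .haplotype_stats import haplotype_spectrum

__all__ = [
    "OutlierRegion",
    "call_regions",
    "intersect_regions",
    "intersect_tests",
    "summarize_region",
]


@dataclass
class OutlierRegion:
    """A scaffold interval (1-based inclusive) flagged by one or more tests."""

    scaffold: str
    start: int
    end: int
    tests: frozenset = frozenset()
    n_snps: int = 0
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"region start {self.start} > end {self.end}")

    def overlaps(self, other: "OutlierRegion") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )

    def jaccard(self, other: "OutlierRegion") -> float:
        """Interval Jaccard index in bp (inclusive coordinates)."""
        if self.scaffold != other.scaffold:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start) + 1
        if inter <= 0:
            return 0.0
        union = (self.end - self.start + 1) + (other.end - other.start + 1) - inter
        return inter / union


def call_regions(scaffold, pos, flagged, merge_gap: int = 50_000,
                 test: str = "") -> list[OutlierRegion]:
    """Merge flagged SNPs within ``merge_gap`` bp into regions (single test)."""
    scaffold = np.asarray(scaffold, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    flagged = np.asarray(flagged, dtype=bool)
    tests = frozenset([test]) if test else frozenset()
    regions: list[OutlierRegion] = []
    for name in dict.fromkeys(scaffold):
        p = np.sort(pos[(scaffold == name) & flagged])
        if p.size == 0:
            continue
        start = prev = int(p[0])
        count = 1
        for q in p[1:]:
            q = int(q)
            if q - prev <= merge_gap:
                prev = q
                count += 1
            else:
                regions.append(OutlierRegion(name, start, prev, tests, count))
                start = prev = q
                count = 1
        regions.append(OutlierRegion(name, start, prev, tests, count))
    return regions


def _interval_intersection(sets: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Intersection of unions of inclusive intervals (each list pre-sorted, disjoint)."""
    current = sets[0]
    for nxt in sets[1:]:
        out = []
        for a0, a1 in current:
            for b0, b1 in nxt:
                lo, hi = max(a0, b0), min(a1, b1)
                if lo <= hi:
                    out.append((lo, hi))
        current = sorted(out)
    return current


def intersect_regions(by_test: dict[str, list[OutlierRegion]]) -> list[OutlierRegion]:
    """Maximal intervals covered by at least one region from every listed test."""
    scaffolds: dict[str, None] = {}
    for rs in by_test.values():
        for r in rs:
            scaffolds.setdefault(r.scaffold, None)
    combined: list[OutlierRegion] = []
    for name in scaffolds:
        per_test = []
        for rs in by_test.values():
            ivs = sorted((r.start, r.end) for r in rs if r.scaffold == name)
            if not ivs:
                per_test = []
                break
            per_test.append(ivs)
        if not per_test:
            continue
        for lo, hi in _interval_intersection(per_test):
            combined.append(OutlierRegion(name, lo, hi, frozenset(by_test)))
    return sorted(combined, key=lambda r: (r.scaffold, r.start))


def intersect_tests(
    regions_fst: list[OutlierRegion],
    regions_pi: list[OutlierRegion],
    regions_xpehh: list[OutlierRegion],
) -> list[OutlierRegion]:
    """Three-way combined call: intervals supported by the FST, pi and XP-EHH tests."""
    return intersect_regions(
        {"fst": regions_fst, "pi": regions_pi, "xpehh": regions_xpehh}
    )


def summarize_region(
    region: OutlierRegion,
    *,
    variants,
    fst_track=None,
    fst_point=None,
    zscore=None,
    xpehh=None,
    pi_focal_track=None,
    hapset=None,
    popmap=None,
) -> dict:
    """Summary statistics of a region: per-test extrema, diversity loss, dominant haplotype.

    pi reduction % compares mean smoothed focal diversity inside the region
    against the same scaffold outside the region; when the region spans every
    SNP on its scaffold the baseline falls back to all other scaffolds (and
    errors if nothing is left).
    """
    inside = (
        variants.mask(region.scaffold)
        & (variants.pos >= region.start)
        & (variants.pos <= region.end)
    )
    out: dict = {
        "scaffold": region.scaffold,
        "start": region.start,
        "end": region.end,
        "tests": ",".join(sorted(region.tests)),
        "n_snps": int(inside.sum()),
    }
    if not inside.any():
        raise DataError(f"region {region.scaffold}:{region.start}-{region.end} has no member SNPs")

    def track_mask(track):
        return (
            (track.scaffold == region.scaffold)
            & (track.pos >= region.start)
            & (track.pos <= region.end)
        )

    if fst_track is not None:
        m = track_mask(fst_track)
        if m.any():
            out["max_smoothed_fst"] = float(fst_track.smoothed[m].max())
    if fst_point is not None:
        vals = fst_point[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out["max_point_fst"] = float(vals.max())
    if zscore is not None:
        m = track_mask(zscore)
        if m.any():
            out["min_z"] = float(zscore.z[m].min())
    if xpehh is not None:
        m = track_mask(xpehh) & xpehh.defined
        if m.any():
            out["max_xpehh"] = float(xpehh.normalized[m].max())
    if pi_focal_track is not None:
        m_in = track_mask(pi_focal_track)
        m_scaf = pi_focal_track.scaffold == region.scaffold
        m_out = m_scaf & ~m_in
        if not m_out.any():
            m_out = ~m_scaf  # genome-wide fallback baseline
            out["pi_baseline"] = "genome"
            if not m_out.any():
                raise DataError(
                    "no outside baseline: region covers every SNP of the only scaffold"
                )
        else:
            out["pi_baseline"] = "scaffold"
        baseline = float(pi_focal_track.smoothed[m_out].mean())
        inside_mean = float(pi_focal_track.smoothed[m_in].mean())
        if baseline > 0:
            out["pi_reduction_pct"] = 100.0 * (1.0 - inside_mean / baseline)
    if hapset is not None and popmap is not None:
        spec = haplotype_spectrum(
            hapset, popmap, variants, region.scaffold, region.start, region.end
        )
        for pop in popmap.populations:
            out[f"dominant_hap_freq_{pop}"] = spec.dominant_frequency(pop)
    return out
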