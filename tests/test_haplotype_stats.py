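import numpy as np
import pytest

from oracles import ehh_pair_counting
from sweepscan.errors import DataError, ValidationError
from sweepscan.haplotype_stats import (
    EHHProfile,
    bifurcation_tree,
    ehh_profile,
    haplotype_spectrum,
    ihh,
    ihh_scan,
    tree_to_lines,
    xpehh_scan,
)
from sweepscan.pipeline import subset_haplotypes
from sweepscan.vcf_io import HaplotypeSet, PopulationMap, ScaffoldInfo, VariantTable


def _hapset(alleles):
    a = np.asarray(alleles, dtype=np.int8)
    samples = [f"s{i}" for i in range(a.shape[0] // 2)]
    return HaplotypeSet(a, samples)


class TestEHH:
    def test_identical_haplotypes_stay_at_one(self):
        hs = _hapset(np.ones((6, 10)))
        prof = ehh_profile(hs, 0, "up")
        assert (prof.ehh == 1.0).all()
        assert prof.truncation == "scaffold_end"

    def test_immediate_truncation_when_all_distinct(self):
        # 00 / 01 / 10 / 11 over [core, core+1]: EHH drops to 0 at the first step
        hs = _hapset([[0, 0, 1], [0, 1, 1], [1, 0, 1], [1, 1, 1]])
        prof = ehh_profile(hs, 0, "up")
        assert prof.ehh[0] == pytest.approx(1 / 3)  # core homozygosity 2*C(2,2)/C(4,2)
        assert prof.ehh[1] == 0.0
        assert prof.truncation == "cutoff"
        assert prof.site_idx.tolist() == [0, 1]

    def test_matches_pair_counting_oracle(self, rng):
        hs = _hapset(rng.integers(0, 2, size=(8, 20)))
        for core, direction in [(10, "up"), (10, "down"), (0, "up"), (19, "down")]:
            prof = ehh_profile(hs, core, direction, cutoff=0.0)
            for idx, e in zip(prof.site_idx, prof.ehh):
                assert e == pytest.approx(
                    ehh_pair_counting(hs.alleles, core, int(idx)), abs=0
                )

    def test_monotone_nonincreasing(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            hs = _hapset(r.integers(0, 2, size=(12, 30)))
            prof = ehh_profile(hs, 15, "up", cutoff=0.0)
            assert (np.diff(prof.ehh) <= 1e-12).all()
            assert ((prof.ehh >= 0) & (prof.ehh <= 1)).all()

    def test_errors(self):
        hs = _hapset([[0, 1], [1, 0]])
        with pytest.raises(ValidationError, match="core index"):
            ehh_profile(hs, 5, "up")
        missing = HaplotypeSet(np.array([[0, -1], [1, 0]], dtype=np.int8), ["a"])
        with pytest.raises(DataError, match="missing"):
            ehh_profile(missing, 0, "up")


class TestIHH:
    def test_single_trapezoid(self):
        up = EHHProfile(0, "up", np.array([0, 1]), np.array([0.0, 1000.0]),
                        np.array([1.0, 0.5]), "scaffold_end", 0.05)
        down = EHHProfile(0, "down", np.array([0]), np.array([0.0]),
                          np.array([1.0]), "scaffold_end", 0.05)
        area, censored = ihh(up, down)
        assert area == pytest.approx(750.0)
        assert censored

    def test_constant_profile_both_sides(self):
        mk = lambda d: EHHProfile(0, d, np.array([0, 1]), np.array([0.0, 10_000.0]),
                                  np.array([1.0, 1.0]), "cutoff", 0.05)
        area, censored = ihh(mk("up"), mk("down"))
        assert area == pytest.approx(20_000.0)
        assert not censored

    def test_core_only_profiles_give_zero_censored(self):
        mk = lambda d: EHHProfile(0, d, np.array([0]), np.array([0.0]),
                                  np.array([1.0]), "scaffold_end", 0.05)
        assert ihh(mk("up"), mk("down")) == (0.0, True)

    def test_distance_doubling_doubles_area(self, rng):
        a = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, 40, replace=False)) + 1
        i1, _ = ihh_scan(a, pos)
        i2, _ = ihh_scan(a, pos * 2)
        np.testing.assert_allclose(i2, 2 * i1, rtol=1e-12)

    def test_scan_matches_profile_integration(self, rng):
        """The jitted per-core scan equals the readable profile + trapezoid path."""
        a = rng.integers(0, 2, size=(10, 25)).astype(np.int8)
        pos = np.sort(rng.choice(60_000, 25, replace=False)) + 1
        hs = _hapset(a)
        scan, censored = ihh_scan(a, pos)
        for core in range(25):
            up = ehh_profile(hs, core, "up", positions=pos)
            down = ehh_profile(hs, core, "down", positions=pos)
            area, cens = ihh(up, down)
            assert scan[core] == pytest.approx(area, rel=1e-12)
            assert censored[core] == cens


def _two_pop_sets(rng, n_sites=60, span=500_000):
    pos = np.sort(rng.choice(span, n_sites, replace=False)) + 1
    vt = VariantTable(np.full(n_sites, "s1", dtype=object), pos,
                      np.full(n_sites, "A", dtype=object), np.full(n_sites, "G", dtype=object))
    info = ScaffoldInfo({"s1": span})
    a = _hapset(rng.integers(0, 2, size=(12, n_sites)))
    b = _hapset(rng.integers(0, 2, size=(12, n_sites)))
    return a, b, vt, info


class TestXPEHH:
    def test_identical_populations_give_zero_raw(self, rng):
        a, _, vt, info = _two_pop_sets(rng)
        pos = vt.pos
        i1, _ = ihh_scan(a.alleles, pos)
        i2, _ = ihh_scan(a.alleles, pos)
        np.testing.assert_array_equal(np.log(i1 / i2), 0.0)
        with pytest.raises(DataError, match="degenerate"):
            xpehh_scan(a, a, vt, info)  # all-zero raw has no spread to standardise

    def test_antisymmetric_under_population_swap(self, rng):
        a, b, vt, info = _two_pop_sets(rng)
        ab = xpehh_scan(a, b, vt, info, min_len=100_000, min_snps=10)
        ba = xpehh_scan(b, a, vt, info, min_len=100_000, min_snps=10)
        np.testing.assert_allclose(ab.raw, -ba.raw, atol=1e-12)

    def test_normalised_scores_standardised(self, rng):
        a, b, vt, info = _two_pop_sets(rng)
        xp = xpehh_scan(a, b, vt, info, min_len=100_000, min_snps=10)
        d = xp.defined
        assert abs(xp.normalized[d].mean()) < 1e-12
        assert abs(xp.normalized[d].std() - 1) < 1e-12

    def test_scaffold_filters_error_when_nothing_passes(self, rng):
        a, b, vt, info = _two_pop_sets(rng)
        with pytest.raises(DataError, match="no scaffolds pass"):
            xpehh_scan(a, b, vt, info, min_len=10_000_000)

    def test_neutral_flag_fraction_bounded(self, small_null_sim):
        sim = small_null_sim
        xp = xpehh_scan(
            subset_haplotypes(sim.hapset, sim.popmap, "PAG"),
            subset_haplotypes(sim.hapset, sim.popmap, "GO"),
            sim.variants, sim.scaffold_info,
        )
        frac = xp.outlier.sum() / xp.defined.sum()
        assert frac <= 0.01 + 1e-9  # positive-sign rule can only shrink the tail

    def test_sweep_scores_colocalise_with_truth(self, small_sim):
        sim = small_sim
        xp = xpehh_scan(
            subset_haplotypes(sim.hapset, sim.popmap, "PAG"),
            subset_haplotypes(sim.hapset, sim.popmap, "GO"),
            sim.variants, sim.scaffold_info,
        )
        t = sim.truth
        inside = (xp.pos >= t.start) & (xp.pos <= t.end)
        q99 = np.quantile(xp.normalized[xp.defined], 0.99)
        assert np.nanmax(xp.normalized[inside]) > q99


class TestSpectraAndBifurcation:
    def test_spectrum_counts_and_dominant(self):
        alleles = np.vstack([np.tile([0, 1], (8, 1)), np.array([[1, 1], [1, 0]]),
                             np.tile([1, 0], (10, 1))])
        hs = _hapset(alleles)
        pm = PopulationMap({f"s{i}": ("PAG" if i < 5 else "GO") for i in range(10)},
                           populations=["PAG", "GO"])
        vt = VariantTable(np.array(["s1", "s1"], dtype=object), np.array([100, 200]),
                          np.array(["A", "A"], dtype=object), np.array(["G", "G"], dtype=object))
        spec = haplotype_spectrum(hs, pm, vt, "s1", 50, 250)
        assert spec.dominant_frequency("PAG") == pytest.approx(0.8)
        assert spec.counts["PAG"]["01"] == 8
        assert spec.counts["GO"]["10"] == 10
        assert sum(spec.frequencies("GO").values()) == pytest.approx(1.0)

    def test_spectrum_matches_pairwise_identity_clustering(self, rng):
        a = rng.integers(0, 2, size=(16, 6)).astype(np.int8)
        hs = _hapset(a)
        pm = PopulationMap({s: "P" for s in hs.sample_ids}, populations=["P"])
        vt = VariantTable(np.full(6, "s1", dtype=object), np.arange(1, 7) * 10,
                          np.full(6, "A", dtype=object), np.full(6, "G", dtype=object))
        spec = haplotype_spectrum(hs, pm, vt, "s1", 1, 100)
        # transitive-closure oracle over exact row identity
        groups = []
        for row in a:
            for g in groups:
                if np.array_equal(row, g[0]):
                    g[1] += 1
                    break
            else:
                groups.append([row, 1])
        assert sorted(spec.counts["P"].values()) == sorted(g[1] for g in groups)

    def test_spectrum_contracts(self, small_sim):
        sim = small_sim
        with pytest.raises(DataError, match="no SNPs"):
            haplotype_spectrum(sim.hapset, sim.popmap, sim.variants, "chr1", 1, 2)

    def test_bifurcation_split_and_conservation(self, rng):
        alleles = np.array([[0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 1], [0, 1]])
        hs = _hapset(alleles)
        tree, truncated = bifurcation_tree(hs, 0, "up", max_extent=1)
        assert not truncated
        (root,) = tree  # single core allele
        assert sorted(c["count"] for c in root["children"]) == [2, 6]

        a = rng.integers(0, 2, size=(14, 9)).astype(np.int8)
        hs = _hapset(a)
        tree, _ = bifurcation_tree(hs, 4, "down", max_extent=4)

        def leaves(nodes):
            out = 0
            for n in nodes:
                out += n["count"] if not n["children"] else leaves(n["children"])
            return out

        assert leaves(tree) == 14
        assert len(tree_to_lines(tree)) >= len(tree)

    def test_bifurcation_no_variation_is_a_path(self):
        hs = _hapset(np.zeros((6, 5)))
        tree, truncated = bifurcation_tree(hs, 0, "up", max_extent=10)
        node, depth = tree, 0
        while node:
            assert len(node) == 1 and node[0]["count"] == 6
            node, depth = node[0]["children"], depth + 1
        assert truncated  # asked for more extent than the matrix holds
        assert depth == 5
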