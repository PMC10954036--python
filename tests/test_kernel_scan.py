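import numpy as np
import pytest

from sweepscan.errors import DataError, ValidationError
from sweepscan.kernel_scan import (
    SmoothedTrack,
    bootstrap_outlier_pvalues,
    gaussian_smooth,
    pi_ratio_zscore,
)


def _track(pos, raw, scaffold="s1", sigma=25_000.0):
    return gaussian_smooth(np.full(len(pos), scaffold, dtype=object),
                           np.asarray(pos), np.asarray(raw, dtype=float), sigma)


def _fake_smoothed(values, spacing=1_000_000):
    """A degenerate track whose smoothed values are set directly (single-member windows)."""
    n = len(values)
    pos = np.arange(1, n + 1, dtype=np.int64) * spacing
    v = np.asarray(values, dtype=float)
    return SmoothedTrack(np.full(n, "s1", dtype=object), pos, v.copy(), v.copy(),
                         np.arange(n), np.arange(n) + 1, 25_000.0)


class TestGaussianSmooth:
    def test_single_snp_identity(self):
        t = _track([500], [3.7])
        assert t.smoothed[0] == 3.7

    def test_constant_track_identity(self):
        t = _track(np.arange(100) * 4000 + 1, np.full(100, 0.42))
        np.testing.assert_allclose(t.smoothed, 0.42, rtol=0, atol=1e-15)

    def test_three_snp_hand_formula(self):
        """0/1/0 at 0/25k/50k with sigma 25 kb: center = 1 / (1 + 2 e^-0.5)."""
        t = _track([1, 25_001, 50_001], [0.0, 1.0, 0.0])
        expected = 1.0 / (1.0 + 2.0 * np.exp(-0.5))
        assert t.smoothed[1] == pytest.approx(expected, abs=1e-12)

    def test_convex_combination_bound(self, rng):
        pos = np.sort(rng.choice(500_000, 300, replace=False)) + 1
        raw = rng.normal(size=300)
        t = _track(pos, raw)
        for c in range(300):
            window = raw[t.win_lo[c]:t.win_hi[c]]
            assert window.min() - 1e-12 <= t.smoothed[c] <= window.max() + 1e-12

    def test_linearity_and_translation_invariance(self, rng):
        pos = np.sort(rng.choice(300_000, 150, replace=False)) + 1
        x, y = rng.normal(size=150), rng.normal(size=150)
        sx, sy = _track(pos, x).smoothed, _track(pos, y).smoothed
        combo = _track(pos, 2.5 * x - 1.25 * y).smoothed
        np.testing.assert_allclose(combo, 2.5 * sx - 1.25 * sy, atol=1e-10)
        shifted = _track(pos + 7_777_777, x).smoothed
        np.testing.assert_allclose(shifted, sx, atol=1e-12)

    def test_windows_never_cross_scaffolds(self):
        scaffold = np.array(["a", "a", "b", "b"], dtype=object)
        pos = np.array([1000, 2000, 1500, 2500])
        t = gaussian_smooth(scaffold, pos, np.array([0.0, 0.0, 5.0, 5.0]))
        np.testing.assert_allclose(t.smoothed, [0, 0, 5, 5])

    def test_empty_and_nonfinite_errors(self):
        with pytest.raises(DataError, match="empty"):
            gaussian_smooth(np.array([], dtype=object), np.array([], dtype=np.int64),
                            np.array([]))
        with pytest.raises(DataError, match="non-finite"):
            _track([1, 2], [1.0, np.nan])


class TestBootstrap:
    def test_bmax_below_first_level(self):
        t = _track([1], [0.5])
        with pytest.raises(ValidationError, match="B_max"):
            bootstrap_outlier_pvalues(t, np.array([0.5]), B_max=50)

    def test_nonfinite_pool_rejected(self):
        t = _track([1], [0.5])
        with pytest.raises(DataError):
            bootstrap_outlier_pvalues(t, np.array([0.5, np.inf]))

    def test_low_window_no_escalation(self, rng):
        """A window below the pool median keeps p ~ 1 at the first level."""
        pool = np.concatenate([rng.normal(size=500), [50.0]])
        t = _fake_smoothed([-10.0])  # far below everything in the pool
        res = bootstrap_outlier_pvalues(t, pool, B_max=100, seed=3)
        assert res.B_used[0] == 100
        assert res.p[0] > 0.9

    def test_tied_maximum_enumeration(self):
        """Single-member window equal to the pool max: p -> P(draw == max) = 1/3."""
        pool = np.array([0.0, 0.5, 1.0])
        t = _fake_smoothed([1.0])
        res = bootstrap_outlier_pvalues(t, pool, B_max=10_000, seed=5)
        # window stops once p > 100/B; at B >= 1000 Monte-Carlo SD is ~0.015
        assert res.p[0] == pytest.approx(1 / 3, abs=0.05)

    def test_p_never_zero_and_extreme_window_escalates(self, rng):
        pool = rng.normal(size=2000)
        t = _fake_smoothed([pool.max() + 10.0])
        res = bootstrap_outlier_pvalues(t, pool, B_max=100_000, seed=1)
        assert res.B_used[0] == 100_000
        assert res.p[0] == pytest.approx(1 / 100_001)

    def test_early_stopping_windows_keep_their_p(self, rng):
        """Raising B_max never changes p for windows that stopped early."""
        pool = rng.normal(size=3000)
        vals = np.concatenate([rng.normal(size=30), [pool.max() + 5]])
        t = _fake_smoothed(vals)
        lo = bootstrap_outlier_pvalues(t, pool, B_max=1000, seed=9)
        hi = bootstrap_outlier_pvalues(t, pool, B_max=100_000, seed=9)
        stopped = lo.p > 0.1  # finished at B = 1000 in both runs
        assert stopped.sum() >= 25
        np.testing.assert_array_equal(lo.p[stopped], hi.p[stopped])
        assert hi.p[-1] < lo.p[-1]  # the extreme window kept escalating


class TestPiRatioZscore:
    def test_standardisation_and_exact_flags(self, rng):
        """1000 N(0,1) windows plus 10 at -8: exactly those 10 flagged."""
        x = np.concatenate([rng.normal(size=1000), np.full(10, -8.0)])
        focal = _fake_smoothed(0.2 * np.exp2(x))
        ref = _fake_smoothed(np.full(1010, 0.2))
        z = pi_ratio_zscore(focal, ref, z_cut=5.0)
        assert abs(z.z.mean()) < 1e-12 and abs(z.z.std() - 1) < 1e-12
        assert set(np.nonzero(z.outlier)[0]) == set(range(1000, 1010))
        assert (z.direction[-10:] == -1).all()

    def test_no_outliers_for_matched_tracks(self, rng):
        base = 0.3 + 0.01 * rng.random(500)
        z = pi_ratio_zscore(_fake_smoothed(base * (1 + 0.01 * rng.random(500))),
                            _fake_smoothed(base))
        assert not z.outlier.any()

    def test_zero_floor_keeps_log_finite(self):
        focal = _fake_smoothed([0.0, 0.2, 0.3, 0.4])
        ref = _fake_smoothed([0.2, 0.2, 0.3, 0.5])
        z = pi_ratio_zscore(focal, ref)
        assert np.isfinite(z.x).all()
        # floored at half the smallest positive value across both tracks
        assert z.x[0] == pytest.approx(np.log2(0.1 / 0.2))

    def test_degenerate_and_mismatched_inputs(self):
        c = _fake_smoothed([0.2, 0.2, 0.2])
        with pytest.raises(DataError, match="degenerate"):
            pi_ratio_zscore(c, c)
        with pytest.raises(ValidationError, match="identical centers"):
            pi_ratio_zscore(c, _fake_smoothed([0.2, 0.2]))
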