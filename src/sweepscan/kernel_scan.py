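"""Gaussian-kernel smoothing, the bootstrap outlier null, and the pi-ratio Z-score.

Smoothing: for a center SNP c, every same-scaffold SNP j with
|pos_j - pos_c| <= 3*sigma contributes weight w_j = exp(-d^2 / (2 sigma^2));
the smoothed value is the weighted mean. Weights below exp(-4.5) are
discarded by the 3-sigma truncation; smoothing never crosses a scaffold
boundary. The center itself is always a member (w = 1).

Bootstrap null: each window's smoothed value is compared against windows of
the same geometry (member count and kernel weights) filled with values drawn
with replacement from the genome-wide pool of per-site values. The p-value
estimator is (1 + k) / (1 + B), never zero, and the replicate count escalates
through B = 1e2, 1e3, ... while the interim p-value satisfies p <= 100/B, up
to ``B_max`` (default 1e7) — cheap for mid-distribution windows, accurate in
the extreme tail. Only the upper tail is scored (high-differentiation
outliers).

Two Monte-Carlo backends produce the replicate draws:

* shallow levels (B < ``shared_level``): a numba loop takes, per replicate,
  a random contiguous slice of a large pre-resampled pool buffer (draws are
  iid pool samples within a replicate; windows use their own random offsets,
  so p-values across windows are effectively independent — this is the path
  exercised by null-calibration checks);
* deep levels: all still-active windows are scored against common random
  draws with one BLAS matrix product per chunk (common random numbers;
  each window's p-value remains a marginally exact estimate, only the joint
  dependence between extreme-tail windows is affected).

Z-score scan: x_i = log2(pi_focal / pi_ref) per window, standardised by the
genome-wide mean and SD of x; windows at Z <= -z_cut (default 5, i.e. the
lower tail, diversity loss in the focal population) are outliers, reported
with |Z|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DataError, ValidationError

__all__ = [
    "SmoothedTrack",
    "ZScoreTrack",
    "BootstrapResult",
    "gaussian_smooth",
    "bootstrap_outlier_pvalues",
    "pi_ratio_zscore",
]

SIGMA_BP_DEFAULT = 25_000.0


@dataclass
class SmoothedTrack:
    """Per-SNP raw and kernel-smoothed values along scaffolds."""

    scaffold: np.ndarray
    pos: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    win_lo: np.ndarray  # first member index (into this track), inclusive
    win_hi: np.ndarray  # last member index, exclusive
    sigma_bp: float

    def __len__(self) -> int:
        return self.pos.size

    def weights(self, c: int) -> np.ndarray:
        """Kernel weights of window c's members (unnormalised)."""
        d = self.pos[self.win_lo[c]:self.win_hi[c]] - self.pos[c]
        return np.exp(-(d.astype(np.float64) ** 2) / (2 * self.sigma_bp**2))


def gaussian_smooth(scaffold, pos, raw, sigma_bp: float = SIGMA_BP_DEFAULT) -> SmoothedTrack:
    """Gaussian-kernel smooth a per-SNP track (undefined sites must be excluded first)."""
    scaffold = np.asarray(scaffold, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    raw = np.asarray(raw, dtype=np.float64)
    if pos.size == 0:
        raise DataError("cannot smooth an empty track")
    if not np.isfinite(raw).all():
        raise DataError("track contains non-finite values; drop undefined sites first")

    smoothed = np.empty_like(raw)
    win_lo = np.empty(pos.size, dtype=np.int64)
    win_hi = np.empty(pos.size, dtype=np.int64)
    offset = 0
    for name in dict.fromkeys(scaffold):
        m = scaffold == name
        p = pos[m]
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise DataError(f"track positions not strictly increasing on {name!r}")
        x = raw[m]
        lo = np.searchsorted(p, p - 3 * sigma_bp, side="left")
        hi = np.searchsorted(p, p + 3 * sigma_bp, side="right")
        s = np.empty(p.size)
        for c in range(p.size):
            d = (p[lo[c]:hi[c]] - p[c]).astype(np.float64)
            w = np.exp(-(d**2) / (2 * sigma_bp**2))
            s[c] = np.dot(w, x[lo[c]:hi[c]]) / w.sum()
        smoothed[m] = s
        win_lo[m] = lo + offset
        win_hi[m] = hi + offset
        offset += p.size
    return SmoothedTrack(scaffold, pos, raw, smoothed, win_lo, win_hi, float(sigma_bp))


@dataclass
class BootstrapResult:
    p: np.ndarray       # final p-value per window, in (0, 1]
    B_used: np.ndarray  # replicates of the level each window stopped at


@njit(cache=True, fastmath=True)
def _boot_buffer(buffer, wflat, wptr, obs, B, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    nwin = obs.size
    L = buffer.size
    k = np.zeros(nwin, dtype=np.int64)
    for c in range(nwin):
        lo = wptr[c]
        m = wptr[c + 1] - lo
        oc = obs[c]
        kc = 0
        for _ in range(B):
            off = np.random.randint(0, L - m + 1)
            s = np.float32(0.0)
            for j in range(m):
                s += wflat[lo + j] * buffer[off + j]
            if s >= oc:
                kc += 1
        k[c] = kc
    return k


def _boot_gemm(pool32, wmat, obs, B, rng, chunk=16384):
    """Common-random-number scoring of many windows via one GEMM per chunk."""
    k = np.zeros(obs.size, dtype=np.int64)
    mmax = wmat.shape[0]
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, pool32.size, size=(b, mmax))
        resampled = pool32[idx]
        scores = resampled @ wmat  # (b, nwin)
        k += (scores >= obs[None, :]).sum(axis=0)
        done += b
    return k


def bootstrap_outlier_pvalues(
    track: SmoothedTrack,
    raw_pool: np.ndarray,
    B_max: int = 10_000_000,
    alpha: float = 1e-5,
    seed: int = 0,
    shared_level: int = 100_000,
    buffer_len: int = 1 << 22,
) -> BootstrapResult:
    """Escalating bootstrap p-values for every window of a smoothed track.

    ``raw_pool`` is the genome-wide pool of defined per-site values.
    ``alpha`` is carried for the caller's outlier rule (p < alpha); it does
    not alter the computation.
    """
    del alpha  # threshold applied by the caller
    raw_pool = np.asarray(raw_pool, dtype=np.float64)
    if not np.isfinite(raw_pool).all():
        raise DataError("raw pool contains non-finite values")
    if raw_pool.size == 0:
        raise DataError("raw pool is empty")
    if B_max < 100:
        raise ValidationError(f"B_max={B_max} below the first escalation level (100)")

    levels = [10**e for e in range(2, 8) if 10**e < B_max]
    levels.append(int(B_max))

    n = len(track)
    # Normalised f32 weights per window, flattened; f32 observed values computed
    # with the identical weights so that exact resample ties compare as ties.
    wlist = []
    obs32 = np.empty(n, dtype=np.float32)
    for c in range(n):
        w = track.weights(c)
        w = (w / w.sum()).astype(np.float32)
        wlist.append(w)
        obs32[c] = np.dot(w, track.raw[track.win_lo[c]:track.win_hi[c]].astype(np.float32))
    wptr = np.zeros(n + 1, dtype=np.int64)
    wptr[1:] = np.cumsum([w.size for w in wlist])
    wflat = np.concatenate(wlist).astype(np.float32)
    mmax = int(max(w.size for w in wlist))

    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2 * len(levels) + 1, dtype=np.uint64)
    buf_rng = np.random.default_rng(state[0])
    L = max(int(buffer_len), 16 * mmax)
    buffer = raw_pool[buf_rng.integers(0, raw_pool.size, size=L)].astype(np.float32)
    pool32 = raw_pool.astype(np.float32)

    p = np.ones(n, dtype=np.float64)
    B_used = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    for li, B in enumerate(levels):
        if active.size == 0:
            break
        obs_a = obs32[active]
        if B < shared_level or active.size <= 64:
            aw = [wlist[c] for c in active]
            awptr = np.zeros(active.size + 1, dtype=np.int64)
            awptr[1:] = np.cumsum([w.size for w in aw])
            awflat = np.concatenate(aw).astype(np.float32)
            kseed = int(state[2 * li + 1] % np.uint64(2**31))
            k = _boot_buffer(buffer, awflat, awptr, obs_a, B, kseed)
        else:
            wmat = np.zeros((mmax, active.size), dtype=np.float32)
            for j, c in enumerate(active):
                wmat[: wlist[c].size, j] = wlist[c]
            gr = np.random.default_rng(state[2 * li + 2])
            k = _boot_gemm(pool32, wmat, obs_a, B, gr)
        p_level = (1.0 + k) / (1.0 + B)
        p[active] = p_level
        B_used[active] = B
        escalate = (p_level <= 100.0 / B) & (B < levels[-1])
        active = active[escalate]
    return BootstrapResult(p=p, B_used=B_used)


@dataclass
class ZScoreTrack:
    """log2 diversity-ratio track standardised genome-wide."""

    scaffold: np.ndarray
    pos: np.ndarray
    x: np.ndarray          # log2(pi_focal / pi_ref), zeros floored
    z: np.ndarray
    outlier: np.ndarray    # Z <= -z_cut (focal diversity loss)
    direction: np.ndarray  # -1 focal loss, +1 focal excess, 0 equal
    mean_x: float
    sd_x: float
    z_cut: float


def pi_ratio_zscore(
    smoothed_focal: SmoothedTrack,
    smoothed_ref: SmoothedTrack,
    z_cut: float = 5.0,
) -> ZScoreTrack:
    """Z-score the log2 ratio of two smoothed diversity tracks on identical centers.

    Zero smoothed values are floored at half the smallest positive smoothed
    value across both tracks (keeps the log finite, preserves rank order).
    A constant ratio track (SD zero) is an error.
    """
    if len(smoothed_focal) != len(smoothed_ref) or not (
        np.array_equal(smoothed_focal.pos, smoothed_ref.pos)
        and np.array_equal(smoothed_focal.scaffold, smoothed_ref.scaffold)
    ):
        raise ValidationError("pi tracks must be smoothed on identical centers")
    f = smoothed_focal.smoothed.copy()
    r = smoothed_ref.smoothed.copy()
    if (f < 0).any() or (r < 0).any():
        raise DataError("negative smoothed diversity values")
    positive = np.concatenate([f[f > 0], r[r > 0]])
    if positive.size == 0:
        raise DataError("both diversity tracks are identically zero")
    eps = 0.5 * positive.min()
    f[f == 0] = eps
    r[r == 0] = eps
    x = np.log2(f / r)
    mean_x = float(x.mean())
    sd_x = float(x.std())  # population SD: Z has mean 0, SD 1 by construction
    if sd_x == 0:
        raise DataError("degenerate ratio track: log2 pi-ratio is constant")
    z = (x - mean_x) / sd_x
    return ZScoreTrack(
        scaffold=smoothed_focal.scaffold,
        pos=smoothed_focal.pos,
        x=x,
        z=z,
        outlier=z <= -z_cut,
        direction=np.sign(x).astype(np.int8),
        mean_x=mean_x,
        sd_x=sd_x,
        z_cut=float(z_cut),
    )
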