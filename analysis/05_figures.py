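#!/usr/bin/env python
"""Track figures for the sweep scan (written to scratch/, not versioned).

Three-panel view of the sweep scaffold — smoothed FST with bootstrap
outliers, per-population smoothed diversity with the log2-ratio Z track,
and normalised XP-EHH with its top-1% threshold — plus the truth interval.
Requires matplotlib (the 'analysis' extra).
"""

from pathlib import Path

import numpy as np

from sweepscan.pipeline import ScanParams, run_scan
from sweepscan.synthetic_data import SimConfig, simulate

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "scratch" / "figures"


def main() -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sim = simulate(SimConfig(seed=SEED))
    res = run_scan(sim.variants, sim.hapset, sim.genotypes, sim.popmap,
                   sim.scaffold_info, "PAG", "GO", ScanParams(B_max=10**5, seed=SEED))
    scaf = sim.truth.scaffold
    fig, axes = plt.subplots(3, 1, figsize=(10, 8), sharex=True)

    m = res.fst_track.scaffold == scaf
    axes[0].plot(res.fst_track.pos[m] / 1e6, res.fst_track.raw[m], ".",
                 ms=2, color="orange", alpha=0.5, label="per-SNP")
    axes[0].plot(res.fst_track.pos[m] / 1e6, res.fst_track.smoothed[m], "k-",
                 label="smoothed (sigma=25 kb)")
    axes[0].set_ylabel(r"$F_{ST}$")
    axes[0].legend(loc="upper left", fontsize=8)

    mz = res.zscore.scaffold == scaf
    axes[1].plot(res.zscore.pos[mz] / 1e6, res.pi_focal_track.smoothed[mz],
                 label="PAG (focal)", color="firebrick")
    axes[1].plot(res.zscore.pos[mz] / 1e6, res.pi_ref_track.smoothed[mz],
                 label="GO (reference)", color="steelblue")
    axes[1].set_ylabel("smoothed pi")
    axes[1].legend(loc="upper left", fontsize=8)

    mx = res.xpehh.scaffold == scaf
    axes[2].plot(res.xpehh.pos[mx] / 1e6, res.xpehh.normalized[mx], ".", ms=3,
                 color="darkgreen")
    axes[2].axhline(res.xpehh.threshold, ls="--", color="gray",
                    label=f"top-1% threshold ({res.xpehh.threshold:.2f})")
    axes[2].set_ylabel("normalised XP-EHH")
    axes[2].set_xlabel(f"{scaf} position (Mb)")
    axes[2].legend(loc="upper left", fontsize=8)

    for ax in axes:
        ax.axvspan(sim.truth.start / 1e6, sim.truth.end / 1e6, color="gold", alpha=0.2)

    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / "sweep_tracks.png"
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
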