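#!/usr/bin/env python
"""Generate the study datasets: a sweep scenario and a matched neutral control.

Two-population (PAG-like focal vs GO-like reference) phased panels at the
default study conditions — 2 x 20 diploids, a 2 Mb scaffold with ~4000 SNPs
plus a 200 kb scaffold, background divergence F = 0.1, and a hard sweep at
0.9-1.1 Mb (dominant-haplotype frequency f = 0.85) in the sweep scenario.

Writes results/data/{sweep,neutral}/: dataset.vcf, popmap.tsv,
scaffolds.tsv, truth.tsv.
"""

from pathlib import Path

from sweepscan.synthetic_data import SimConfig, simulate, write_dataset

SEED = 42
ROOT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    for label, config in [
        ("sweep", SimConfig(seed=SEED)),
        ("neutral", SimConfig(seed=SEED).no_sweep()),
    ]:
        result = simulate(config)
        paths = write_dataset(result, ROOT / label)
        print(f"{label}: {len(result.variants)} SNPs, "
              f"{len(result.hapset.sample_ids)} samples -> {paths['vcf'].parent}")
        if result.truth:
            t = result.truth
            print(f"  sweep truth: {t.scaffold}:{t.start}-{t.end} "
                  f"in {t.population} at f={t.f}")


if __name__ == "__main__":
    main()
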