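# sweepscan

Selective-sweep detection for two-population panels of phased biallelic
SNPs, built for reduced-representation (RAD-style) data where a focal
population is suspected of recent local adaptation against a reference
population — e.g. a thermally extreme coral population versus conspecifics
on neighbouring, milder reefs.

A recent hard sweep leaves three complementary footprints around the
selected locus, and the pipeline tests all three and intersects them:

1. **Differentiation** — per-SNP Weir–Cockerham F_ST, Gaussian-kernel
   smoothed (σ = 25 kb) along each scaffold and compared with an
   escalating bootstrap null: each window's smoothed value is re-scored
   against windows of identical geometry filled with values resampled from
   the genome-wide pool, with replicates escalating 10² → 10⁷ so that only
   tail windows pay for precision. Outliers: bootstrap *P* < 10⁻⁵.
2. **Diversity loss** — variant-site nucleotide diversity
   π = (n/(n−1))·2pq per population, smoothed on shared centers;
   x = log2(π_focal/π_ref) standardised genome-wide,
   Z = (x − x̄)/s.d.(x). Outliers: Z ≤ −5 (focal diversity loss).
3. **Extended haplotypes** — XP-EHH: raw = ln(iHH_focal/iHH_ref) at every
   core SNP, where iHH integrates extended haplotype homozygosity over
   physical distance to an EHH cutoff of 0.05, normalised genome-wide.
   Outliers: |score| in the top 1% with positive sign, on scaffolds
   > 300 kb with > 20 SNPs.

Flagged SNPs merge into regions (50 kb gap), and the **combined call** is
the interval-level intersection of the three region sets, summarised by
per-test extrema, percent diversity loss and dominant-haplotype
frequencies. A separate module tests selection on methylation substrate:
per-site counts of intact "CG" dinucleotides at designated CpG positions,
compared between populations with exact Fisher tests, plus a ≥4-fold
screen on per-position mean methylation.

Everything runs end to end on synthetic data from the built-in simulator
(Balding–Nichols divergence, founder-mosaic LD, configurable hard sweep
with known truth), so the whole pipeline is testable without any external
dataset. See `docs/methods.md` for the models and numerical conventions.

## Worked example

```bash
sweepscan simulate --seed 42 --out-dir data/       # 4400 SNPs, 2x20 diploids, sweep at 0.9-1.1 Mb
sweepscan scan --vcf data/dataset.vcf --popmap data/popmap.tsv \
    --scaffold-lengths data/scaffolds.tsv --seed 42 --b-max 1000000 \
    --out-dir scan/
```

prints

```
wrote 4 files to data/ (4400 SNPs)
scan complete: 388 FST / 0 pi / 40 XP-EHH outlier SNPs; 0 combined region(s)
```

meaning: the bootstrap flagged 388 SNPs at *P* < 10⁻⁵ (they merge into one
region spanning ~894–1103 kb, almost exactly the simulated sweep), XP-EHH
flagged its top-1% tail inside the same interval, and the π-ratio Z-score
— whose genome-wide standardisation loses power when a sweep occupies ~10%
of a toy genome — flagged nothing, so the strict three-test intersection
is empty at this scale. `scan/tracks.tsv` holds every per-SNP statistic;
`scan/regions_*.tsv` the per-test and combined regions; `scan/manifest.json`
every threshold applied. The same steps are scripted as a narrative under
`analysis/` (simulate → scan → region reports → CpG tests → figures),
writing tables to `results/`.

For the library API:

```python
from sweepscan import ScanParams, run_scan
from sweepscan.synthetic_data import SimConfig, simulate

sim = simulate(SimConfig(seed=42))
res = run_scan(sim.variants, sim.hapset, sim.genotypes, sim.popmap,
               sim.scaffold_info, focal="PAG", ref="GO",
               params=ScanParams(B_max=10**6, seed=42))
print(res.xpehh.threshold)        # empirical top-1% |XP-EHH| threshold: 3.00
print(res.regions["fst"][0])      # OutlierRegion(scaffold_1, 894109-1103404, ...)
```

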