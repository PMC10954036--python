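# Methods

`sweepscan` detects candidate selective sweeps in a two-population panel of
phased biallelic SNPs by intersecting three statistics that respond to
different footprints of positive selection, and separately tests for
selection on methylation substrate at designated CpG sites. This note
records the model choices, parameter meanings and numerical conventions, in
the package's own terms.

## Coordinates and data model

All coordinates are 1-based inclusive (the VCF convention); BED output
converts at the boundary. Only biallelic SNPs are analysed; multi-allelic
and indel records are skipped with a logged count, never split. Missing
genotypes are tolerated in the diploid dosage matrix — per-site statistics
use per-site non-missing allele counts — but rejected by haplotype-length
statistics, where pair identity is undefined under missingness.

## Per-site statistics

**FST** is the Weir–Cockerham (1984) variance-component estimator θ =
a/(a+b+c) for two populations, computed from per-population sample sizes,
allele frequencies and observed heterozygosities. A site is defined when
both populations have ≥ 2 genotyped diploids and the pair is polymorphic.
Negative per-site estimates (sampling noise around zero differentiation)
are **retained by default**: clamping them at zero would bias the
genome-wide pool that the bootstrap null resamples from. A
`clamp_negative_fst` switch exists for display.

**Nucleotide diversity** is the variant-site form π = n/(n−1) · 2pq with n
the non-missing allele copies — identical to the mean pairwise difference
over all C(n,2) haplotype pairs (an identity the tests verify exactly).
There is no per-bp normalisation; the scan compares like with like across
windows of the same SNP track. Sites with n < 2 are undefined, not zero.

## Gaussian-kernel smoothing

Each per-SNP track is smoothed with weights w = exp(−d²/2σ²) over
same-scaffold neighbours within 3σ (≈ discarding weights < e^−4.5), σ =
25 kb by default — a scale suited to fragmented assemblies. The smoothed
value is a convex combination of the window's raw values; smoothing never
crosses scaffold boundaries; a lone SNP smooths to itself. Window members
are weighted by the kernel only, not additionally by per-site allele
counts; with balanced panel sizes the extra weighting would be nearly
constant, and keeping the kernel pure keeps the bootstrap geometry exact.

## Bootstrap outlier null for smoothed FST

The null asks: how often would a window of *this* geometry (member count
and kernel weights), filled with per-site values drawn with replacement
from the genome-wide pool of defined per-site FST values, smooth to at
least the observed value? The estimator p = (1+k)/(1+B) is never zero, so
a call of P < 10⁻⁵ is only possible once B ≥ 10⁶ — which is exactly the
point of the escalation schedule: every window starts at B = 100 and
advances through 10³ … up to `B_max` (default 10⁷) only while its interim
p ≤ 100/B. Mid-distribution windows stop at B = 10³; only the extreme tail
pays for millions of replicates. Only the upper tail is scored.

Replicates come from two backends chosen per escalation level:

* B < 10⁵ — a numba loop draws, per replicate, a random contiguous slice of
  a large buffer that was itself resampled from the pool (slice entries are
  iid pool draws); every window uses its own offsets, so p-values across
  windows are effectively independent. The null-calibration test (KS
  uniformity on isolated windows) runs entirely on this path.
* B ≥ 10⁵ — all still-active windows are scored against **common random
  draws** with one BLAS matrix product per chunk of replicates. Common
  random numbers leave each window's p-value a marginally exact Monte-Carlo
  estimate; only the joint dependence between extreme-tail windows is
  affected, which no downstream decision uses. This is what makes
  million-replicate escalation affordable on one core.

Exact ties between a resampled and the observed smoothed value count as
exceedances; the observed value is computed with the same single-precision
weights the resampler uses so that ties are bit-exact.

## π-ratio Z-score scan

Per window, x = log2(smoothed π_focal / smoothed π_ref); Z = (x − x̄)/s.d.(x)
with the plain genome-wide mean and population SD, so the Z track has mean
0 and SD 1 by construction. Outliers are the lower tail Z ≤ −z_cut
(default 5): diversity loss in the focal population, reported with |Z|.
Zero smoothed values are floored at half the smallest positive smoothed
value across both tracks, keeping the log finite while preserving rank
order. A constant ratio track is an error, not a silent zero.

A caveat that matters at small genome sizes: the plain mean/SD are
computed over *all* windows, so when a swept region occupies a nontrivial
fraction of the track (here ~10% of windows at the default 2.2 Mb / 200 kb
configuration), the region inflates s.d.(x) and caps attainable |Z| near
√((1−φ)/φ) for contaminated fraction φ — around 4 at these sizes,
independent of sweep strength. The 5-SD rule therefore only regains its
power on genome-scale tracks where φ is negligible; at desk scale the FST
and XP-EHH tests carry the detection. We keep the plain standardisation
because it is the method's definition and the Z-track moment invariants
depend on it.

## EHH, iHH and XP-EHH

EHH at extension k from a core SNP is Σ_h C(n_h,2)/C(n,2) over groups of
haplotypes identical across the closed span [core..k]; it starts at the
core-site homozygosity and is non-increasing. iHH integrates EHH over
physical distance by trapezoid, both directions summed, stopping at the
first value below the cutoff (default 0.05; the crossing segment is
included). Cores whose decay runs into a scaffold end are kept but flagged
boundary-censored (power there is compromised); a strict mode drops them.

XP-EHH uses pooled EHH (all haplotypes, not allele-partitioned) per
population: raw = ln iHH_focal − ln iHH_ref, exactly antisymmetric under
population swap. Raw scores are standardised by their genome-wide mean and
SD (unbinned; an allele-frequency-binned variant is not implemented because
the pooled statistic does not condition on a core allele). Outliers are
cores whose |normalised| score reaches the empirical (1 − top_fraction)
quantile (default top 1%) **and** whose sign is positive — extended
haplotypes in the focal population. The applied quantile is reported; a
fixed constant would just be one dataset's realisation of it. Scaffolds
must exceed 300 kb and 20 SNPs before any score is computed. No gap-scaling
penalty is applied between distant SNPs: with reduced-representation data
large gaps are the norm, and the cross-population contrast absorbs shared
gap structure.

The per-core scan is numba-compiled (incremental identity-group refinement,
O(haplotypes) per extension step); a readable profile-based path implements
the same definitions and the tests require exact agreement between the two.

## Regions and the combined call

Flagged SNPs merge into regions when within `merge_gap` = 50 kb (2σ, so
regions are scale-consistent with the smoothing kernel); region bounds snap
to member SNP positions. The combined call intersects the three single-test
region sets at the interval level — maximal intervals simultaneously
covered by at least one region from each test — and the report records
which member SNPs carry individual triple flags. Region summaries include
per-test extrema, the dominant exact-string haplotype frequency per
population, and percent diversity loss, measured as smoothed focal π inside
vs outside the region on the same scaffold (genome-wide fallback when a
region spans its whole scaffold).

## The simulator

The synthetic-data generator produces the study conditions end to end:
positions uniform per scaffold; ancestral frequencies Beta(0.8, 0.8)
truncated to [0.05, 0.95]; per-population frequencies from the
Balding–Nichols model with divergence F; K founder haplotypes per
population drawn site-wise; sample haplotypes as founder mosaics with
copy-switch probability 1 − exp(−ρd) between adjacent SNPs and per-site
flip noise μ. Defaults: 2 × 20 diploids, one 2 Mb scaffold at 2000 SNPs/Mb
plus one 200 kb scaffold (which exercises the XP-EHH length filter by
construction), K = 12, F = 0.1, ρ = 10⁻⁵/bp, μ = 5 × 10⁻⁴.

The hard sweep collapses the focal population onto founder #1 inside the
sweep interval: each focal haplotype is, with probability f (default 0.85),
a copy of founder #1 re-mutated at μ_s = 10⁻⁴. The remaining residual
haplotypes are *not* fully ancestral: real sweeps leave recombinant
escapees that share most of the swept haplotype, and fully ancestral
residuals would cap diversity loss at ≈ 1 − f² (~72%), far from the ~95%
loss a strong sweep shows next to an ~85% dominant haplotype. Residuals
therefore track founder #1 but switch segmentally into their own
background mosaic with stationary ancestral fraction `residual_ancestry`
(default 0.3, segment lengths governed by ρ). Expected within-interval
diversity ratio is ≈ 2ε(1−ε) with ε = (1−f)·residual_ancestry ≈ 0.045,
i.e. ~91–96% loss, while the dominant exact haplotype stays near f.

Two model properties worth knowing. First, finite founder pools add a
background differentiation floor of ≈ 1/(2K) from founder-sampling drift
(~0.07 at K = 12), so realised mean FST at F = 0.1 is ≈ 0.16; the
estimator-null test uses a large K to isolate estimator behaviour. Second,
the generator emulates differentiation, diversity and decaying LD but not
demography (growth, migration, hotspots), sequencing error, depth variation
or RAD locus dropout — so passing recovery tests demonstrate the scan
machinery end to end at the simulated effect sizes, not performance on any
particular empirical dataset.

All randomness flows from one seed; identical config + seed reproduces
every output file byte-identically.

## CpG-intactness selection test

Methylated cytosines deaminate to thymine an order of magnitude faster
than unmethylated ones, so designated methylated CpG sites are mutable: a
haplotype either retains the intact "CG" dinucleotide or carries a
disrupted variant (typically "TG"). Counting intact vs disrupted haplotypes
per population at each site gives a 2×2 table tested with a Fisher exact
test — two-sided by the point-probability convention (sum of hypergeometric
point probabilities ≤ the observed one, relative tie tolerance 10⁻¹²,
enumerated over the full feasible range; one-sided tails are exposed).
Counting is haplotype-level: a heterozygous individual contributes one unit
to each category. Ambiguous bases drop a haplotype from that site's
denominator with a log. The companion screen reports the squared Pearson
correlation of per-position mean methylation between populations and flags
positions with ≥ 4-fold focal excess (a reference mean of zero with
positive focal mean counts as an outlier). Bisulfite processing is out of
scope; the methylation table is an input abstraction the fixture generator
also produces.

## Problem sizes and runtime

The default validation scale — 4400 SNPs, 80 haplotypes, bootstrap
escalation capped at B = 10⁶ in the recovery runs (10⁷ remains the library
default) — keeps a full three-test scan near 15 s on one core and a
40-run recovery study around 5 minutes, while leaving every threshold at
its standard value (σ = 25 kb, Z ≤ −5, top 1% positive XP-EHH,
P < 10⁻⁵). B = 10⁶ is the smallest ceiling at which the p-estimator can
fall below 10⁻⁵, so the cap does not change any call.

## Known limitations

* The Z-score's plain standardisation loses power when the swept fraction
  of the track is large (see above) — a property of the statistic, visible
  only at toy genome sizes.
* The bootstrap's common-random-number backend correlates p-values between
  extreme-tail windows; marginal values (and hence all calls) are unaffected.
* Exact-string haplotype dominance is sensitive to the interval width:
  over narrow intervals the dominant class absorbs residual haplotypes and
  its frequency exceeds the sweep's generative f.
* The simulator's founder-mosaic LD is exponential-ish in distance and has
  no hotspot structure; EHH decay rates are realistic in order of
  magnitude, not in fine shape.
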