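# Methods

This note documents the models and conventions implemented in `atcmap`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Coordinates and data conventions

All genomic intervals are 0-based half-open internally; human-readable
reports print 1-based inclusive coordinates. Expression enters as raw
RSEM-like nonnegative values and is transformed as log₂(x + 1); the
pseudocount keeps zeros finite. Copy number lives on fixed 100-kb segments
with 0 meaning diploid and positive values amplified; a gene's copy-number
vector is the segment containing its midpoint (midpoint rule: deterministic
and strand-free; nearest segment on the same chromosome if the grid has a
gap).

## Exact univariate k-means (`ckmeans1d`)

An optimal 1-D k-means partition is contiguous in sorted order, so the
global optimum is computed by dynamic programming: `cost[m, i]` = minimal
WCSS of the first *i* + 1 sorted values in *m* + 1 clusters, with O(1)
segment costs from prefix sums of centered values (centering avoids
catastrophic cancellation at genomic magnitudes). Ties between equal-cost
splits resolve to the leftmost boundary, making results fully
deterministic. Complexity O(k·n²); the package clusters at most a few
hundred positions per chromosome, where this is milliseconds.

### Choosing k

Positions of genes inside an amplified region, or of binding sites inside a
hub, are approximately **uniform** over the region — not Gaussian.
Gaussian-mixture likelihoods are miscalibrated for such data: the
likelihood gain from splitting a uniform blob in half (≈ n·ln 2 in the
exponent) almost exactly cancels the mixture-proportion loss, leaving the
choice to noise. Measured on planted clusters of ~25 points, BIC variants
(pooled variance, per-cluster variance, EM-fitted mixtures) recovered the
true cluster count only 66–91% of the time.

`select_k` therefore uses a penalized-dispersion (elbow) rule that exploits
the geometry directly: the selected k is the **largest k in range whose
optimal WCSS is below 0.1 × the optimal WCSS at k − 1**. Merging two real
clusters inflates WCSS by the squared separation (orders of magnitude above
within-cluster spread in genomic aggregations: measured true-split ratios
were ≤ 0.065 across all planted scenarios), while splitting a real cluster
shaves at most a factor ~4; the measured false-trigger rate is < 1% for
clusters of ≥ 20 points. Two guards make the rule safe at the boundaries:
candidate k whose optimal partition contains a cluster of fewer than 3
points are inadmissible (isolating singletons/pairs always produces a large
drop — including the terminal drop to WCSS 0 at k = n — but is overfitting,
not aggregation), and a constant vector resolves to k = 1. The
Gaussian-mixture BIC of the chosen partition (pooled variance floored at
1e-9, 2k parameters) is still computed and reported as a diagnostic.

With only ~8 points per cluster the rule mis-splits ~8–13% of the time;
that ambiguity is irreducible at such n (eight uniform points genuinely can
look like two tight groups) and is why hub calling is most reliable with
tens of consensus sites per chromosome.

## Geomapping thresholds (`atc_geomapper`)

* r ≥ 0.6 **inclusive** for the ATC screen; correlations are undefined (and
  the gene dropped) for zero-variance vectors or fewer than 3 complete
  pairs after pairwise deletion.
* Region criteria: gene count ≥ 15; span strictly < 20 Mb; density strictly
  > 1 × 10⁻⁸. Span is max member gene end − min member gene start.
* Density is a Gaussian KDE (Silverman bandwidth) over the chromosome's
  ATC-gene positions in bp, evaluated at member positions and maximised per
  region. A per-bp KDE naturally lives on the 10⁻⁸ scale of the threshold;
  a genes-per-bp ratio would make that cutoff vacuous. Coincident positions
  (zero spread) are treated as infinitely dense and arbitrated by the gene
  count criterion.
* Clustering input is gene **start** positions; screening is joint over all
  samples (not stratified by ER status).
* Regions are named A, B, C, … in genomic order.

## ERα hubs (`eralpha_hubs`)

"Common" binding sites are maximal intervals covered by ≥ 1 peak from
**each** of the three sources simultaneously (strict three-way base-pair
intersection, minimum overlap 1 bp) — chosen over pairwise-overlap chaining
because it is symmetric, deterministic and idempotent. Hubs are clusters of
site midpoints (same selection rule), spanning the extremes of their member
sites; chromosomes with fewer sites than the k-range lower bound emit a
single hub with a warning.

## Rearrangement counting (`rearrangements`)

* Confidence filter: score strictly > 80 (BreakDancer convention).
* An event contributes to a bait if either breakpoint lies inside it
  (half-open containment); the partner end is binned into 1-Mb bins
  anchored at coordinate 0, or into the enclosing hub ("non_hub"
  otherwise). Both ends in the *same* bait count once, in the intra
  stratum; ends in two *different* baits count once per bait. Breakpoints
  beyond a supplied chromosome length clamp into the last bin with a
  warning.
* Group comparison is a two-sided Mann-Whitney U (scipy): exact enumeration
  when both groups have ≤ 10 samples, otherwise the tie-corrected normal
  approximation. Per-sample counts are raw (no depth normalization).

## Concordance and survival (`concordance_survival`)

"Cumulative normalized expression" is operationalized as the per-sample sum
of per-gene z-scores with the **population**-SD convention (divide by n);
the score is therefore invariant to per-gene affine rescaling, and
zero-variance genes contribute 0 with a warning. ATC-prone/ATC-less groups
are the top/bottom n (default 15) by score, ties broken by sample id.
Correlation profiles are pairwise Pearson matrices in genomic gene order,
optionally on a sample subset (e.g. the top 10 by score); undefined entries
from flat genes are NaN. Survival stratification splits at the median
(score > median → high) and compares groups with the standard two-group
log-rank test (lifelines; chi-square with 1 df). The chi-square p-value is
an asymptotic approximation: at very small n it can differ from the exact
permutation p by more than Monte-Carlo error, which is a property of the
test, not of the implementation — the test suite validates the statistic
against an independent direct-formula oracle and its placement in a
10,000-permutation null.

## The synthetic cohort (`synthetic_cohort`)

Defaults are the baseline study conditions: 200 samples; 1,000 genes of
fixed 10-kb length on two chromosomes (80 + 60 Mb); three planted regions
(8 Mb each, 30 member genes, dosage slope 0.8); log2-scale expression noise
SD 0.5; per-region per-sample gain probability 0.5 with amplitude
uniform(0.3, 1.5); background segments gain independently with probability
0.05; a weak shared latent factor (SD 0.3) gives background genes
CN-independent co-expression. ER⁺ fraction 0.6. Rearrangements: Poisson
per-sample counts (mean 20 for ER⁺, 3× lower for ER⁻); 70% of ER⁺ events
put one breakpoint uniformly in a planted region and the other in a planted
hub, the rest fall uniformly (chromosome ∝ length); 20% of confidence
scores fall ≤ 80 to exercise the filter. Peaks: 10 hubs of 2 Mb carry 8
shared 500-bp sites each, jittered ±200 bp per pseudo cell line, plus 50
line-specific noise peaks. Survival is exponential with hazard =
(1/1500 days) · exp(0.5 · z) where z is the standardized cumulative score
of the coupled genes, censored by an independent exponential tuned to ~30%
censoring. At these settings a planted gene's expected screen correlation
is ≈ 0.63 — deliberately close to the 0.6 threshold, so recovery is
informative rather than trivial; occasional loss of a region to the
15-gene criterion is the expected behaviour of a marginal signal.

The manifest records, per planted region, the **member-gene span** (min
start to max end of the planted genes) and, per hub, the **site span**;
recovery is judged against these rather than the configured containers,
whose gene-/site-free flanks are undetectable in principle (even a perfect
noise-free run caps at Jaccard (n−1)/(n+1) ≈ 0.94 against an 8-Mb container
holding 30 uniform genes, and the container midpoint of 8 uniform sites is
only localizable to ~160 kb).

Everything is reproducible from the seed; identical configs give
byte-identical files (fixed float formatting, sorted YAML keys).

**What the generator does not emulate:** RNA-seq count noise models
(negative binomial overdispersion), tumor purity/ploidy, subclonal copy
number, LOH/deletions (only gains), realistic SV breakpoint mechanisms or
read-level evidence, ChIP-seq signal strength, and gene-length variation.
Passing tests show the pipeline recovers planted dosage-coupled structure
under Gaussian noise at realistic effect sizes; they do not certify
performance on real tumor data with those additional artifacts.

## Problem sizes

Tests and the acceptance script run replicate cohorts of 200 samples ×
1,000 genes (10 replicates for recovery, 10 for the null, 100–500 light
replicates for test calibration), which keeps the full suite under a
minute on one core while leaving every statistical check at meaningful
power.

## Known limitations

* The k-selection threshold (0.1) presumes cluster separations well above
  cluster widths; regimes with gaps comparable to spans (e.g. adjacent
  amplicons) will under-split.
* The density criterion depends on the KDE bandwidth; with very few ATC
  chromosomes-wide the Silverman bandwidth is wide and the density of a
  true region can approach the 10⁻⁸ threshold.
* Mann-Whitney exact enumeration does not tie-correct (scipy behaviour);
  with many tied counts and small groups, prefer the asymptotic path.
* The log-rank p is asymptotic (see above); for very small cohorts use a
  permutation test directly.
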