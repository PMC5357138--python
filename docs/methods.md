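# Methods

## Scope and data model

The pipeline analyzes a cell-line panel described by four aligned objects:
a gene-level log2 relative copy-number matrix (genes × samples, diploid
baseline, so single-copy loss sits near log2(1/2) = −1), a gene-level
dependency-score matrix (ATARiS-style: more negative = more dependent), a
sample annotation (lineage per cell line), and — for the splicing component
— a juncBase-style junction table of per-sample inclusion/exclusion read
counts by event class. Genomic intervals are 0-based half-open everywhere,
including SEG input, so the length of [a, b) is exactly b − a. Missing
values are "NA" in all TSVs; every operation documents its NA policy.

## General association screen

All pairs (copy-number gene, dependency gene) are correlated with Pearson's
r on pairwise-complete samples. Pairs with fewer than
`min_pairwise_samples` (default 20) complete observations, or a
zero-variance vector, are emitted as NA and excluded from the FDR family.
p-values use the two-sided t reference with n−2 degrees of freedom; BH is
applied once over all non-NA pairs. The vectorized masked-matrix
computation is pinned to a scalar per-pair oracle at 1e-12 in the tests.

Direction is read off the correlation sign: dependency scores decrease with
dependence, so r > 0 (lower copy number with lower score) is
loss-associated and r < 0 gain-associated. Relation is cis when both genes
share a chromosome.

Large copy-number events make many neighboring genes carry the same
association with one dependency profile. Significant records (q <
`fdr_general`, default 0.25) are therefore collapsed per dependency gene:
its significant copy-number genes are grouped by chromosome, sorted
genomically, and adjacent members are linked transitively when their
copy-number profiles correlate at r ≥ `collapse_r_min` (default 0.9) — the
transitive closure makes one arm-level event one region. Each region
nominates a source gene: the dependency gene itself if it lies in the
region, else a paralog of it (from an explicit two-column map, symmetric
closure applied), else the member with the smallest q.

## CYCLOPS screen

Copy states per gene: loss when log2 ≤ `loss_threshold` (−0.35; the
boundary is a loss), gain when log2 ≥ `gain_threshold` (+0.35), neutral
otherwise. Gain lines are excluded from both groups so amplified lines do
not dilute "neutral"; setting `gain_threshold = +inf` restores a strict
two-class scheme. The statistic is the delta dependency score, the
loss-group mean minus the neutral-group mean — the quantity screens of this
kind plot — rather than a rank statistic.

The null preserves the panel's lineage composition: in each permutation the
loss/neutral labels are shuffled independently within every lineage
stratum, keeping per-stratum group counts exact (a stratum whose labels are
all one class contributes no shuffling; if every stratum is degenerate the
p-value is NA). The test is one-sided toward negative delta, with the
add-one estimate p = (1 + #{Δ_b ≤ Δ_obs})/(B + 1). B defaults to 10,000,
resolving p to 1e-4, which is what a q < 0.1 cut at genome scale needs;
the implementation draws within-stratum label subsets via a vectorized
partition trick, so a 500-gene × 179-line screen at B = 10,000 runs in
seconds. Genes with fewer than two copy-loss lines are excluded and carry
no p or q. BH runs across tested genes; candidates are q < `fdr_cyclops`
(default 0.1).

Cross-screen validation declares a primary hit validated when the secondary
screen shows delta in the same (negative) direction with one-sided
permutation p < α = 0.05, and reports k/n with a one-sided exact binomial
proportion p against the null rate α.

## Splicing framework

PSI for a junction in a sample is k/(k + excl), NA when no reads. Sampling
is modeled as BetaBinomial(n, π, ρ) in the mean/overdispersion
parameterization Beta(πθ, (1−π)θ) with θ = (1−ρ)/ρ, which reduces exactly
to Binomial(n, π) at ρ = 0 (the boundary is a legal MLE and is compared
explicitly during fitting). Maximum likelihood uses bounded L-BFGS-B from a
method-of-moments start; a single observation cannot identify ρ, which is
then fixed at 0 with a warning.

Each junction is tested with a likelihood ratio between a null (shared π)
and an alternative (group-specific π), p from χ²(1). The dispersion is
**held fixed while testing the mean**: letting the alternative re-fit ρ
absorbs between-group variance into the dispersion and inflates the
statistic at the small group sizes typical of these designs (measured
type-I 0.095 at α = 0.05 with 5 vs 5 samples at depth 50), while
re-estimating ρ under the full model is worse (0.123). With ρ fixed at the
junction's pooled null estimate the test is calibrated (0.050) but loses
power when a true shift inflates the pooled estimate. The screen therefore
shares a **common dispersion across junctions** — the median over junctions
of the group-mean-adjusted method-of-moments ρ, so real inclusion shifts do
not contaminate it — and tests each junction at that value; measured type-I
is 0.066 with power 0.95 at a planted ΔPSI of 0.3 (depth 50, 6 vs 6). The
standalone `junction_lrt` defaults to the per-junction null estimate and
accepts an external ρ; a parametric-bootstrap flag exists for small-sample
checking. A `per_junction` screen mode retains the standalone behavior.

BH families are per event class (intron retention, alt 3′, alt 5′, cassette
exon), matching how junction families are reported separately. The
significance threshold is a config value defaulting to q < 0.1 (a stricter
0.01 is sometimes used for display; the choice is explicit, not baked in).
Direction-count comparisons use the exact one-sided binomial tail
P(X ≥ max(a, b)) at p₀ = 0.5, computed entirely in log space from
log-gamma terms with a truncated summation window (12 SD past k, omitted
mass negligible at double precision), so magnitudes like 10^−1110 are
exact and finite. Junction-level counts are reported as such; no
junction→transcript rollup is attempted because no principled rule is
available without annotation.

## Characterization statistics

Expression uniformity "normalized to expression level" is CV² =
variance/mean² on the linear scale by default, with a `variance_of_log`
strategy flag for comparison. The copy-number→expression response is the
percent decrease 100·(1 − mean_loss/mean_neutral), NA unless both groups
have ≥ 2 samples and the neutral mean is positive, plus the per-gene
Pearson r against continuous copy number. Fraction of genome lost is the
summed half-open length of segments at or below the loss threshold over the
genome length; loss-event sizes are measured relative to the containing
arm (a centromere-spanning event exceeds 1; a whole chromosome scores 2).
A gene counts as lost when loss segments cover ≥ 50% of its length
(`gene_loss_overlap_fraction`) — the rule is explicit because no standard
exists. Gene-set enrichment is the upper-tail hypergeometric test with BH
across sets, against an explicitly supplied universe (the appropriate
universe is analysis-dependent and never assumed). Mutual exclusivity uses
the minimum-likelihood two-sided Fisher convention; overlap proportions use
the exact binomial tail.

## Synthetic panel generator

The generator emulates the statistical structure the screens assume, with
defaults set to the study conditions: 179 cell lines across 4 lineages; 10
chromosomes × 2 arms × 25 genes tiling 1 Mb slots; per-arm whole-arm loss
probability 0.15 plus focal losses (rate 0.1, 5–20% of the arm), together
calibrated so the mean fraction of genome lost is ≈ 0.16 (expected value
0.161; a 200-sample Monte-Carlo check holds it within ±0.03); loss
segments at log2 = −1 with segment noise SD 0.05 and per-gene measurement
noise SD 0.05, and no homozygous deletions, mirroring essential-gene loss
patterns. Dependency scores are Gaussian (SD 0.3) — scores of this kind
are roughly centered continuous values and no noise model is published —
with planted loss-conditional shifts of −1.15 (the scale of the strongest
observed splicing-factor dependency, group means −1.14 vs 0.01) for 10
CYCLOPS genes and −0.9 for 5 trans pairs. Expression is log-normal with
fractional loss attenuation 0.28 for planted CYCLOPS genes vs 0.18 for
background, and CYCLOPS genes get half the log-noise SD (the
uniformly-expressed class). Junction counts are Poisson totals (mean depth
50) with beta-binomial inclusion (ρ = 0.05), 2000 junctions cycled over
four event classes, 10% dysregulated by ΔPSI = 0.3, 90% of shifts up in
the target group; shifts that leave (0, 1) are clipped with a warning.

Per-lineage loss-rate multipliers exist but default to 1; near-polyploid
genomes, shRNA-level (pre-gene-score) data and mutation calls beyond a
binary indicator are out of generator scope. Every generator is a pure
function of (config, seed); planted truth is emitted beside the data and
recovery tests read it rather than re-deriving it.

What passing tests on this generator do **not** show about real data:
real panels have lineage-correlated copy-number structure, non-Gaussian
score noise, GC- and mappability-driven junction-count artifacts, and
dependency effects that vary with genetic background; the generator's
clean conditional effects mean recovery rates here are upper bounds on
real-data performance.

## Numerical and design notes

- Permutation p-values live on {1,…,B+1}/(B+1); KS comparisons against
  U(0,1) are biased by at most 1/(B+1), negligible at B ≥ 1000.
- The all-pairs correlation guards cancellation by flagging variances below
  1e-12 of scale as degenerate (NA) and clips r into [−1, 1].
- BH q-values come from the step-up rule with NAs excluded from the family
  size m (logged).
- Byte-identical re-runs: output tables carry only seed/config-hash
  provenance (no timestamps), and every random draw descends from the run
  seed.
- Analysis problem sizes (500 genes × 179 lines, 2000 junctions, B =
  10,000; B = 1000 and 50 replicates in calibration studies) are chosen as
  desk-scale defaults that keep every property measurable with comfortable
  Monte-Carlo margins.

## Known limitations

The collapse rule (adjacency + r ≥ 0.9, transitive) is one reasonable
formalization of "identical significant associations"; panels with
long-range copy-number correlation may merge regions a human would split.
The loss/gain direction rule presumes dependency scores oriented
more-negative = more-dependent. The χ²(1) reference for the splicing LRT
is asymptotic; at very low depths (< 10 reads) the bootstrap flag is the
safer route. Copy-state calling is not ploidy-aware: a single-copy loss in
a tetraploid genome will not reach the −0.35 threshold.
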