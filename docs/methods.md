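# Methods

## Phenotypes and data model

The raw unit is a long-format table of replicated crown measurements
(specimen × tooth × dimension × replicate × observer, values in mm).
Replicates and observers are averaged into one value per variable; rows of
(M1, M2, M3) sizes are then assembled per specimen for one of two metrics:

- **length** — mesiodistal crown length (the molar module component, MMC,
  phenotype), mm;
- **area** — the rectangular estimate, mesiodistal length × buccolingual
  width (the classical inhibitory-cascade phenotype), mm².

Specimens missing any of the three lower molars are excluded from row-level
analyses; a missing width excludes a specimen from the area metric only.
Ratio phenotypes per specimen are r21 = M2/M1, r31 = M3/M1, and the
relative sizes rel_i = M_i / (M1+M2+M3), which sum to 1 by construction.
Units are fixed (mm, mm²); there is no unit autodetection.

### Repeatability

Measurement error is summarized by ANOVA percent repeatability.  For each
tooth position a one-way ANOVA with specimen as the grouping factor pools
all replicate × observer measurements as within-group error; the
among-specimen variance component is the Lessells–Boag estimator
s²_A = (MS_among − MS_within)/n₀ with n₀ the replicate-weighted group size,
and repeatability is R = s²_A / (s²_A + MS_within), averaged over the three
teeth and clipped to (0, 1].  Observers are deliberately pooled into the
error term, so R captures error both within and between observers — the
same quantity later used to deflate posterior variances.  A two-way variant
(`compute_repeatability_two_way`) removes per-observer offsets first and is
exposed for sensitivity analysis; it is not the default because the
downstream correction multiplies variances by total measurement
repeatability, offsets included.

## The six-prediction test

Predictions about means use the linear gradient M3 = 2·M2 − M1; those about
second moments follow from applying it to a covariance matrix:

    var(M3)     = 4·var(M2) + var(M1) − 4·cov(M1,M2)
    cov(M1,M3)  = 2·cov(M1,M2) − var(M1)
    cov(M2,M3)  = 2·var(M2)  − cov(M1,M2)

**Posterior.** (M1, M2, M3) sizes are modeled jointly Gaussian.  A
two-block Gibbs sampler draws from the posterior under a flat prior on the
mean vector μ and a weak inverse-Wishart prior on the covariance Σ — scale
10⁻³·I (covariances zero), degrees of freedom 3.002, i.e. just above the
dimension.  Full conditionals are conjugate:

    μ | Σ, X  ~  N(x̄, Σ/n)
    Σ | μ, X  ~  IW(ν₀ + n,  S₀ + Σᵢ(xᵢ−μ)(xᵢ−μ)ᵀ)

Inverse-Wishart draws use the Bartlett decomposition.  The weak prior scale
also regularizes rank-deficient samples: data lying exactly on the ICM
plane (M3 a linear combination of M1, M2) have a singular sample covariance
yet a proper posterior.  A coordinate with zero sample variance, by
contrast, is rejected with an error — that degeneracy signals a data
problem, not a prior question.

Function defaults mirror a long-MCMC protocol (burn-in 500,000, every
1,000th draw kept, 1,000 draws).  Because this sampler is conjugate
two-block Gibbs, its autocorrelation is negligible (lag-1 autocorrelation
of Σ elements ≈ 0; effective sample size ≈ nominal), so the analysis
scripts and tests run it at burn-in 200–2,000 and thinning 2–10, which
yields statistically equivalent draws at a fraction of the cost.  Those
problem sizes are recorded here as the package's own choice.

**Measurement-error adjustment.** Every posterior variance draw is
multiplied by the metric's repeatability; covariances and means are left
untouched.  Applying r then r′ equals applying r·r′.  A side effect worth
knowing: the adjusted (var1, var2, cov12) block of a draw need not remain a
mathematically valid covariance, so the prediction formulas are evaluated
as linear expressions per draw rather than through the validity-checked
public function.

**Report.** Per draw, each observed quantity is divided by its theoretical
counterpart: μ₃ vs 2μ₂−μ₁; μ₂/Σμ vs 1/3; delta-method var(rel M3) vs
var(rel M1); and the three covariance-structure formulas.  Relative-size
variances use the delta method on tooth/(row total) — gradient
g_j = (δ_ij·T − μ_i)/T², variance gᵀΣg — rather than re-simulating
individuals per draw; a Monte-Carlo cross-check is cheap to add but the
delta method is exact in the small-CV regime these data occupy (CV ≈ 3–8%).
Each ratio distribution is summarized by its Gaussian-KDE mode (Silverman
bandwidth, argmax on a 512-point grid) and 95% HPD (shortest contiguous
interval over the sorted draws); the prediction is *consistent* when the
HPD contains 1.  A parameter whose theoretical value is non-positive in
more than 5% of draws is reported **unstable** and never called
consistent: when the denominator straddles zero the ratio's credible
interval is unbounded and a verdict would be meaningless.  This situation
arises naturally for cov(M1,M3), whose theoretical value 2·cov12 − var1
changes sign at corr(M1,M2) = sd1/(2·sd2).

**RMA regression.** Predictions 1–2 use reduced major axis (model II)
regression in (r21, r31) space: slope = sign(corr)·SD(y)/SD(x), intercept
through the means.  Confidence intervals are seeded bootstrap percentile
intervals over specimens (9,999 resamples by default) and the association
p-value is a permutation test (999 permutations of y).  The bootstrap CI is
a deliberate substitute for lmodel2-style analytic/permutation CIs; it is
symmetric in x and y up to resampling noise and satisfies
slope(y∼x)·slope(x∼y) = 1 exactly at the point estimate.

## Standing variation and pooling

CVs (100·SD/mean, n−1 denominator) are computed per ratio for the pooled
sample and each locality/sex subsample.  A one-sided exact sign test asks
whether subsample CVs are consistently below the pooled CV (ties dropped).
Group differences in ratio values use pairwise Mann–Whitney U tests —
exact enumeration when both groups have n ≤ 20 and no ties, the
tie-corrected normal approximation otherwise — with Bonferroni correction
applied within each ratio separately.  The U reported is that of the first
(row) group.  The sample is pooled unless any corrected p falls below α
for either ratio.  A pooled-sample ratio CV above 15% raises an
*over-averaging* flag (time, space, or sex may be conflated in the
sample); the flag is reported, never used to exclude data automatically.
Zero ratios (an absent M3) are retained in CVs and flagged; an exclusion
variant is available.

## Sampling-design simulations

**Reference intervals.** The full sample's 95% reference intervals are
constructed per statistic (default `method='population'`):

- *mean*: population-scale, mean ± 1.96·SD of the per-specimen ratios.
  The question a worker asks of a small sample's mean is whether it lands
  within the species' range of variation; against a CI-of-the-mean
  (width ∝ 1/√n), subsample means would be "adequate" only at N close to
  the full n, which contradicts the observed behaviour of molar ratio
  data and would make the composite question vacuous.
- *SD*: seeded bootstrap percentile CI (10,000 resamples) of the sample
  SD — variance structure is exactly the quantity whose estimation error
  is at issue, so its interval is the sampling uncertainty of the
  statistic.

An all-bootstrap construction and a normal-theory mean CI remain available
behind the `method` flag, and the choice is recorded in the result.

**Sample-size adequacy.** For each N in 2..n−1, 10,000 subsamples are
drawn without replacement; the proportions of pseudoreplicate means and
SDs outside the reference intervals are recorded, and the adequacy
threshold is the smallest N with ≤5% outside (first crossing, non-monotone
sequences logged).  Subsampling without replacement carries a
finite-population effect: at N = n the proportions are exactly 0, which is
used as an internal consistency check.

**Composite molar rows.** For each N in 1..50, 1,000 outer replicates draw
N teeth per tooth position *independently* with replacement — a composite
cannot know specimen identity, which is precisely the fossil scenario —
and the composite point estimate is the ratio of per-position means
(not the mean of ratios, matching how a composite row would actually be
assembled).  An inner loop resamples one tooth per position 1,000 times to
form the pseudosample whose SD stands in for the sample SD.  Proportions
of outer replicates outside the reference intervals are tabulated per N.
A `paired=True` validation mode keeps specimen identity in both loops and
recovers the complete-row behaviour.  Independence across positions
destroys the within-specimen correlation of tooth sizes, so the
pseudosample SD estimates the spread of decorrelated ratios — larger than
the true ratio SD whenever teeth covary positively — and composite samples
therefore never recover variance structure, at any N.

## Synthetic generator

`simulate_rows` produces complete molar rows in three modes:

- `icm_exact`: (M1, M2) bivariate Gaussian; M3 = 2·M2 − M1 + ε with
  ε ~ N(0, residual_sd_m3²).  At residual_sd_m3 = 0 every specimen lies
  exactly on the ICM plane and all six predictions hold by construction
  (for the relative-size variances this follows from the row total being
  3·M2 on the plane, whence rel3 = 2/3 − rel1).
- `activator_inhibitor`: per-specimen a/i ~ N(a_over_i, a_over_i_sd²)
  applied to the linear gradient and scaled by a Gaussian M1; all (r21,
  r31) pairs fall exactly on r31 = 2·r21 − 1.
- `mvn`: (M1, M2, M3) jointly Gaussian with arbitrary mean and SPD
  covariance.

Negative draws are rejected and resampled (logged; warned above 10%); a
log-scale switch exists for robustness experiments.  Group (locality)
offsets shift means; explicit group sizes are rescaled proportionally if
they disagree with `n_specimens`.

Defaults emulate the study system the pipeline was designed around — a
small cricetid rodent sampled across four localities (20/20/10/20, n=70),
M1 length 1.55 mm with 5% CV, M2/M1 ≈ 0.8 (hence M3/M1 ≈ 0.6 on the ICM
line), residual_sd_m3 = 0.04 mm of biological scatter off the plane, and
replicate noise calibrated to 93% repeatability.  Two defaults deserve
comment:

- `m1_m2_corr = 0.8`.  The theoretical cov(M1,M3) changes sign at
  corr = sd1/(2·sd2) ≈ 0.625 under the default gradient; a generator
  whose exact-ICM output is meant to satisfy all six predictions must sit
  clearly on the positive side.  0.8 is within the range reported for
  adjacent-tooth integration within populations, but it is at the strong
  end: one visible consequence is that composite *mean* estimates, whose
  spread is inflated by decorrelation roughly by
  √[(cv1²+cv2²)/(cv1²+cv2²−2ρ·cv1·cv2)], need larger N here (≈5–10) than
  in weakly integrated samples before 95% fall inside the reference
  interval.
- `width_ratio = 0.65` with 0.02 mm noise: width is a fixed proportion of
  length, so area ratios are approximately the squares of length ratios.
  This makes the synthetic area metric deviate from the ICM even when
  lengths sit near the plane — a deliberately pessimistic stand-in, since
  real widths carry partly independent (body-size-linked) variation.

The replicate-noise generator inverts the repeatability estimator:
σ²_within = σ²_among·(1−R)/R with σ²_among estimated per tooth × dimension
across specimens, so `compute_repeatability` recovers the target in
expectation (round-trip accuracy ±0.03 at 70 specimens × 6 measurements).

What the generator does *not* emulate: measurement-outlier processes,
M3 agenesis (zero ratios are an input-data situation, not generated),
non-Gaussian size distributions, allometric width–length coupling, and
time-averaging of fossil accumulations.  Passing tests on this generator
therefore demonstrate the correctness and calibration of the machinery,
not that any particular real sample meets or violates the ICM.

## Pipeline and reproducibility

`run_pipeline` executes data → repeatability → ratios → pooling → ICM test
→ simulations from one config; a single global seed spawns per-stage seeds
via numpy's `SeedSequence.spawn` in a fixed stage order, so any stage can
be re-run in isolation and identical config + seed reproduces every output
byte for byte.  Both metrics run by default.  Errors abort with the stage
name; outputs of earlier stages remain on disk.  All simulation sizes
(bootstrap resamples, pseudoreplicates, outer/inner loops, posterior
draws) are configurable; the analysis scripts use 10,000 pseudoreplicates
per N and 1,000×1,000 composite loops, while the test-suite and acceptance
runs use reduced sizes chosen so that Monte-Carlo error stays an order of
magnitude below every asserted tolerance.

## Known limitations

- The delta-method relative-size variances are first-order; at ratio CVs
  above ~20% the approximation error becomes comparable to posterior
  spread.
- The unstable-parameter rule (theoretical value ≤ 0 in >5% of draws) is a
  reporting convention; alternative conventions (e.g. signed-ratio HPDs)
  would flag the same parameters but summarize them differently.
- The exact Mann–Whitney path requires tie-free data; tied samples fall
  back to the tie-corrected normal approximation regardless of size.
- Area repeatability is computed on replicate-paired length × width
  products, which assumes replicates of the two dimensions are taken
  together (true of the generator and of protocols that measure both per
  session).
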