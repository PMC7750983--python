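# molarcascade

Tools for testing the **inhibitory cascade model (ICM)** of mammalian molar
size covariation at the intraspecific scale, and for deciding what kind of
sample — how many complete molar rows, or how many isolated teeth — such a
test actually needs.

## The scientific problem

Mammalian lower molars develop sequentially, and the ICM proposes that a
constant balance of activator and inhibitor signalling makes their sizes
follow a linear gradient along the tooth row,

```
s_x = 1 + [(a - i)/i](x - 1),   x = 1, 2, 3   =>   M3 = 2·M2 - M1
```

At the level of a population sample this single rule implies a suite of
testable predictions about means, variances, and covariances of the crown
sizes (M1, M2, M3), here indexed 1–6:

1. the association between M2/M1 and M3/M1 explains significant variation;
2. the reduced major axis (RMA) line in (M2/M1, M3/M1) space has slope 2
   and intercept −1;
3. μ(M3/M1) = 2·μ(M2/M1) − 1;
4. M2 is one third of the total molar row;
5. var(relative M3) = var(relative M1);
6. var(M3) = 4·var(M2) + var(M1) − 4·cov(M1,M2),
   cov(M1,M3) = 2·cov(M1,M2) − var(M1),
   cov(M2,M3) = 2·var(M2) − cov(M1,M2).

Predictions 3–6 are tested in a Bayesian framework: a Gibbs sampler draws
from the posterior of the Gaussian mean vector and covariance matrix of
(M1, M2, M3), posterior variances are deflated by the ANOVA repeatability of
the measurements, and each observed quantity is divided by its theoretical
counterpart per draw.  A prediction is *consistent* when the 95% highest
posterior density (HPD) interval of that ratio contains 1.  The molar module
component (MMC) variant applies the same machinery to mesiodistal crown
lengths instead of rectangular crown areas (length × width).

Because intraspecific samples — especially fossil ones — are small and
fragmentary, the package also implements two sampling-design simulations:

- **sample-size adequacy**: subsample the full sample without replacement
  at every N and ask when 95% of pseudoreplicate means/SDs fall inside the
  full sample's 95% reference intervals;
- **composite molar rows**: mimic a collection of isolated teeth by drawing
  N teeth per tooth position independently, form the composite ratio from
  per-position means, and estimate spread from an inner "pseudosample"
  resampling — the only spread estimate available to someone holding
  isolated fossils.

A synthetic generator produces molar rows with known structure (exact-ICM,
activator–inhibitor, or arbitrary Gaussian), locality/sex grouping, and
replicate measurement noise calibrated to a target repeatability, so every
stage is testable without access to any particular collection.

## Worked example

The numbered scripts under `analysis/` run the whole study design on a
synthetic cotton-mouse-style sample (70 specimens from four localities,
triplicate measurements by two observers at ~93% target repeatability) and
write their tables under `results/`:

```
$ python analysis/01_simulate_dataset.py
wrote 2520 replicated measurements for 70 specimens
repeatability (length): 0.926
repeatability (area): 0.962

$ python analysis/02_ratios_and_pooling.py
[length] n=70; median r21=0.803, r31=0.599; pooling decision: pool
[area]   n=70; median r21=0.640, r31=0.361; pooling decision: pool (over-averaging CV flag raised)

$ python analysis/03_icm_test.py
[length] RMA slope 2.129 (CI 1.851..2.428; predicted 2), intercept -1.107 (predicted -1); 5/6 predictions consistent
[area]   RMA slope 1.512 (CI 1.334..1.691; predicted 2), intercept -0.608 (predicted -1); 1/6 predictions consistent

$ python analysis/04_sample_size_adequacy.py
[length] smallest adequate N: {'r21_mean': 2, 'r21_sd': 35, 'r31_mean': 2, 'r31_sd': 37}

$ python analysis/05_composite_rows.py
[length r21] mean outside at N=1: 0.407; SD outside range over grid: 0.805..1.000
```

Reading those numbers: the generator plants lengths near the ICM plane, so
the length metric recovers the ICM line (slope CI covers 2, intercept CI
covers −1) and passes five of six predictions; the area metric, whose
ratios are roughly the squares of the length ratios, fails most predictions
and its cov(M1,M3) ratio is reported *unstable* because its theoretical
value straddles zero — exactly the situation in which a consistency verdict
would be meaningless.  Mean molar ratios are adequately estimated from as
few as 2 complete rows, while SDs need ~35 specimens, and composite rows
built from isolated teeth never recover the variance structure (SD-outside
proportions stay far above 5% at every N) even though their point estimates
of the mean tighten steadily with N.

The same operations are scriptable over any measurement CSV via the CLI:

```
molarcascade simulate --seed 9 --out measurements.csv
molarcascade ratios measurements.csv --metric area --out ratios.csv
molarcascade icm-test measurements.csv --metric length --out icm.json
molarcascade cv measurements.csv --out cv.csv --report pooling.json
molarcascade samplesize-sim measurements.csv --out adequacy.csv
molarcascade composite-sim measurements.csv --out composite.csv
molarcascade run --seed 1 --out results/
```

Input CSVs are long-format with the header
`specimen_id,locality,sex,tooth,dimension,replicate,observer,value_mm`
(tooth ∈ {M1,M2,M3}, dimension ∈ {length,width}).

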