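# Methods

`vinephen` implements a desk-scale, fully synthetic replica of a UAV
phenotyping workflow for single-staked vine crops (the motivating system is
white Guinea yam, *Dioscorea rotundata*): multi-view canopy imaging, canopy
feature extraction, machine-learning shoot-biomass estimation, and
hierarchical Bayesian growth-curve characterization. Because the package is
validated entirely on simulated data, this note records the models, the
defaults and why they were chosen, and what the passing tests do — and do
not — establish about real field data.

## The growth model

Shoot biomass of genotype *g* at time *t* (days after transplanting, DAP) is

f(t; θ_g) = A_g (1 + ν_g e^{−k_g (t − t_i,g)})^{−1/ν_g} · e^{−d_g (t − t_d,g)}

a Richards (generalized logistic) rise multiplied by an exponential
senescence term, with

| parameter | meaning | unit | generator default (population mean) |
|---|---|---|---|
| A | asymptotic maximum biomass | g/plant | 130 |
| ν | curvature/asymmetry of the rise | — | 1.5 |
| k | intrinsic growth-rate constant | 1/day | 0.07 |
| t_i | inflection time (max growth rate) | DAP | 105 |
| d | decay-rate constant | 1/day | 0.01 |
| t_d | decay onset | DAP | 193 |

The curve is evaluated in log space
(`log f = log A − log1p(ν e^{−k(t−t_i)})/ν − d(t−t_d)`), so large
`|k (t − t_i)|` neither overflows nor goes negative.

**Decay modes and identifiability.** Two readings of the decay term are
implemented. `as_printed` applies `e^{−d(t−t_d)}` at every *t* (the factor
exceeds 1 before `t_d`); `gated` replaces the factor by 1 for `t < t_d`, so
`t_d` is literally the onset of decay. `as_printed` is the package default
for curve evaluation, but it has a structural flaw for inference: since
`e^{−d(t−t_d)} = e^{d t_d} e^{−d t}`, the likelihood constrains only the
products `(A e^{d t_d}, d)` — A and t_d form a one-dimensional ridge resolved
solely by the priors. In practice that ridge produces slow mixing (max
split-R̂ ≈ 1.9 at the default design) and prior-driven bias in A. The
recovery harness and the acceptance run therefore use `gated` mode, under
which all six parameters are identified (max split-R̂ ≈ 1.08, A recovered
within 15% for 12/12 genotypes in the reference run). Users fitting real
series should prefer `gated` unless they specifically want the ridge.

## Hierarchical Bayesian estimation

Observations are modelled as `y ~ Normal(f(t; θ_g), σ_obs)` (homoscedastic
Gaussian). Genotype parameters are pooled on the transformed scale
φ = (log A, log ν, log k, t_i, log d, t_d):

- φ_g = μ0 + τ ⊙ z_g with z_g ~ N(0, I) (non-centered parameterization);
- μ0 ~ Normal(m0, s0) elementwise with data-driven centers: log of the
  maximum observed biomass for log A; the time of the steepest rise of the
  pooled mean trajectory for t_i; ten days before the last observation for
  t_d; log 0.07 and log 0.01 for log k and log d; broad scales
  (1.0, 1.0, 1.0, 30 d, 1.5, 20 d);
- τ ~ Half-Normal(0.5, 0.5, 0.5, 10 d, 0.5, 10 d) elementwise — the
  between-genotype covariance is **diagonal** in this implementation (scales
  only, no correlation matrix); a full Σ0 is accepted by the simulator but
  not estimated;
- σ_obs ~ Half-Normal(sd of the observed y).

Sampling uses a hand-written No-U-Turn sampler: multinomial sampling over
the doubling trajectory, dual-averaging step-size adaptation targeting 0.8
acceptance, and a diagonal mass matrix estimated in expanding warm-up
windows (Stan-like schedule). The log-posterior gradient is analytic and is
verified against central finite differences in the test suite (relative
error ≤ 1e−4 at randomly chosen coordinates). Energy errors beyond 1000 are
treated as divergences and terminate the trajectory. Initialization jitters
around the prior centers; up to four retries re-jitter on a non-finite
start.

Default sampler configuration: 4 chains × 3,000 iterations with 500 warm-up
steps (10,000 retained draws); a reduced profile (4 × 1,000, 500 warm-up)
is provided for quick runs. The likelihood collapses records onto unique
(genotype, time) cells with sufficient statistics (count, Σy, Σy²) — exact,
and roughly an order of magnitude faster when plants share acquisition
dates — so the full configuration fits the default series design in about
five minutes on one CPU. Convergence is summarized
as per-parameter split-chain Gelman–Rubin R̂ and effective sample size
(computed by arviz); parameters with zero sampling variance are flagged
undefined rather than folded into the maximum.

Records are sorted internally by (genotype, plant, replicate, time), so
fits are invariant to input row order; with a fixed seed they are
bit-reproducible.

## The synthetic-data generator

The generator emulates the data-generating structure the downstream stages
assume — not radiative transfer, photogrammetry, weather, or soil processes.

**Field design.** A split-plot randomized complete block design: fertilizer
on main plots, genotype on subplots, 12 genotypes × 2 treatments × 3 blocks
= 72 plots of 3 × 3 m holding 16 plants at 1 m spacing (a (side+1)² grid
including plot edges). Destructive sampling draws 4 plants per plot at each
of 2 stages (60 and 120 DAP) in each of 2 years — 1,152 sampled plants —
never re-sampling a plant within a year.

**Canopy patches.** Each plant is rendered as a 1.4 m square patch (RGB
reflectance + DEM) containing the 1 × 1 m extraction polygon. The canopy
surface is a cylinder/cone blend (architecture coefficient 1 → cylinder)
over a circular footprint; leaves cover a Bernoulli fraction of footprint
pixels. Soil sits on a flat 0.40 m ridge. Vegetation and soil RGB are drawn
from fixed green- and brown-centered Gaussians (sd 0.03) — only the rank
structure of the indices matters for the tests, so no attempt is made at
spectral realism. View dependence is modelled as (i) an additive DEM height
bias per view (−0.20 m oblique, −0.30 m nadir, −0.10 m combined) and (ii)
occlusion dropout of the lowest canopy pixels (20% / 30% / 8%), which
reproduces the qualitative finding that combined-view reconstructions
recover more canopy height than either single view.

**Growth series.** 12 genotypes × 8 plants × 3 replicates × 11 time points
= 3,168 records, with θ_g drawn from Normal(μ0, Σ0) on the transformed
scale and Gaussian observation noise (default σ_obs = 13 g/plant, 10% of
the mean A). The 11 acquisition dates run from 14 to 196 DAP with mixed
2–3-week gaps. This window deliberately extends past the decay onset
(~193 DAP): an 11-point series at 2–3-week spacing cannot both resolve the
senescence phase and stop at week 18, and the decay parameters are only
estimable if the window reaches them. An optional heteroscedastic mode
scales the noise by `0.5 + f/f_peak`, emulating inter-plant spread that
peaks around maximum biomass; the fitted likelihood remains homoscedastic
either way, which is a deliberate (mild) model mismatch available for
robustness checks.

**Feature tables for the regression stage.** Rendering and extracting 3,456
patches per replicate would dominate runtime, so the regression stage is fed
by a direct simulator: latent biomass per sampled plant (genotype ×
treatment × stage × year effects with lognormal spread) drives true canopy
descriptors, which are degraded per view by occlusion-driven height
shrinkage (12% / 22% / 4% for oblique / nadir / combined) and feature noise
(10% / 15% / 5%). The combined view is least degraded by construction —
the regression ordering test therefore checks that the *pipeline* converts
an information advantage into a test-set R² advantage, not that such an
advantage exists in nature. The raster route (render → extract) is
exercised end-to-end on a subset of plants in the pipeline smoke run.

## Feature extraction

Seven variables per plant and view: projected canopy area A_proj (m²), four
RGB indices, and two heights (m).

- Index forms: GRVI = (G−R)/(G+R); GLI = (2G−R−B)/(2G+R+B);
  VARI = (G−R)/(G+R−B); GSI = (G−gray)/(G+gray) with
  gray = a·R + (1−a)·B. The GSI form is a single-weight grayscale contrast;
  its weight a defaults to 0.635 and can be optimized over a grid
  (default 0–1 in steps of 0.005) by maximizing the Pearson correlation of
  per-patch GSI with A_proj, ties broken toward the smaller weight.
- Vegetation masking: Otsu's threshold on the per-pixel GLI image, floored
  at GLI = 0.2 so vegetation-free patches do not split their soil noise; a
  fixed-threshold mode is available. This is a reproducible stand-in for
  interactive thresholding.
- Per-plant index values are means over vegetation-mask pixels (a
  whole-polygon option is not provided; the mask convention is the
  documented one). Pixels whose index denominator is within 1e−9 of zero
  are excluded from that index's mean.
- Heights: ground is the 5th percentile of the in-polygon DEM
  (configurable); per-pixel heights are clipped at zero; H_max/H_ave are
  max/mean over vegetation pixels inside the polygon.
- Grid conventions: local metric coordinates, row-major, origin top-left;
  a pixel belongs to the polygon iff its center does.

Extraction is pure per patch: the same patch yields the same feature vector
regardless of batch composition (GSI weight optimization is explicitly
collection-level).

## Biomass regression

Protocol: random 80/20 split (train size rounds half up), standardization
to zero mean/unit variance **fitted on the training subset only** (the
anti-leakage reading; zero-variance features are dropped with a warning),
exhaustive grid search with seeded 5-fold CV selecting the minimum mean CV
RMSE, evaluation on the held-out subset by R² (about the test mean) and
RMSE on the response scale, plus post-hoc subgroup metrics (per year,
stage, treatment, genotype; groups under n = 3 suppressed). Grids: SVR
C ∈ {1,5,10,50,100}, γ ∈ {0.01,0.05,0.1,0.5,1}; RF 500 unpruned trees,
mtry 1–4 (impurity importances recorded, not used for selection); XGB
learning rate {0.01,0.1,0.3} × depth {3,6,9} × γ {0,0.1,0.2} × subsample
{0.6,0.8,1.0} × min child weight {1,3,5} × column subsample {0.6,0.8,1.0}
(100 boosting rounds). Stepwise regression is bidirectional under
AIC = n·log(RSS/n) + 2(p+1), greedily taking the best add/drop until no
move lowers AIC; exact duplicate columns are removed first. Note that AIC
admits each irrelevant predictor with probability ≈ P(χ²₁ > 2) ≈ 0.16, so
the selected set can carry a small number of noise features even under a
strong, sparse signal; the tests assert support recovery and bounded model
size rather than exact-set selection.

Shapley attributions are computed in-package: the exact closed form
`φ_j = β_j (x_j − mean background_j)` for linear models, and a seeded
permutation-sampling estimator for kernel/tree models that values a
coalition by the mean prediction over a training background sample.
Because each permutation's marginal contributions telescope, additivity
(baseline + Σφ = prediction) holds to floating-point precision for any
number of permutations; the permutation count (default 20) controls only
the variance of the per-feature split.

All estimators run single-threaded with fixed seeds, making SVR/stepwise
runs bit-reproducible and RF/XGB reproducible given the fixed thread count.

## Pipeline

`vinephen run-all --config run.yaml --seed N --out DIR` executes
simulate → extract → train → fit-growth → summarize. One global seed
derives per-stage seeds by SHA-256 hashing of the stage name, so stages
re-run independently and reproducibly. Every run writes a normalized
config, plain-text artifacts (CSV/JSON, TIFF rasters for patches), and a
manifest with the config hash, per-file SHA-256 digests, package versions
and timestamps. Stage failures abort with the stage name; completed outputs
are retained, and `--resume` skips stages whose outputs exist. Default
configs are deliberately small (4 genotypes, 1 year, reduced MCMC) so a
full run completes in a few minutes; the study-scale counts are plain
config overrides.

## Problem sizes used by the tests and the acceptance script

The convergence/recovery acceptance runs use the full series design (3,168
records) with the full sampler configuration (4 × 3,000, 500 warm-up) —
about five minutes on one CPU. The draw-count check runs the same
configuration on a 2-genotype, 10-record series. The
regression-ordering check trains the full SVR grid on all three views for
ten seeded replicates of the 1,152-plant feature dataset. Oracle-equivalence
checks cover 50 seeded patches at 2 cm resolution against per-pixel Python
loops.

## Known limitations

- The generator's color model and canopy geometry are schematic; passing
  tests certify the pipeline's internal consistency and statistical
  machinery, not photogrammetric realism. Absolute R²/RMSE values on
  synthetic features are not comparable to field results.
- The hierarchy estimates genotype scales only (diagonal Σ0); among-genotype
  parameter correlations are simulated but not recovered.
- `as_printed` decay is faithful to the printed curve but structurally
  unidentified in (A, t_d); inference defaults should be `gated` (see above).
- Time is handled internally in DAP; day-of-year input must be shifted by
  the transplant date before fitting.
- The permutation Shapley estimator inherits the usual caveat that marginal
  perturbation of correlated features can create unrealistic composites;
  attributions on strongly collinear indices should be read qualitatively.
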