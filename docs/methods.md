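# Methods

This note records the statistical model, the numerical choices behind the
sampler, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left the design open.

## Model

The outcome is a per-fish binary indicator of any visible external
anomaly (DELT). All three model variants share the logit-linear form

    Pr(y = 1) = logit⁻¹(β₀ + X_j β + γ_k + φ_r + η_s),

with crossed, mean-zero normal random effects for collection agency
(γ_k), ecoregion (φ_r) and species (η_s). Random effects are mean-zero
by prior only; no sum-to-zero constraint is imposed, so the intercept
and the effects are identified jointly through partial pooling. The
observation year is carried as metadata (the study window is a filter,
2008–2019 by default) but does not enter the linear predictor. Predictors
are static per-stream values of upstream-watershed attributes; multi-year
attributes are first collapsed to the unweighted mean of their annual
values.

Variants: *unconditional* (no predictors; used for occurrence-probability
tables), *conditional* (predictors with the regularized horseshoe prior),
*species-specific* (conditional form fitted to a single focal species —
naive prevalence ≥ 5% and n strictly > 100 — without the species effect).

### Priors

| parameter | prior | default | notes |
|---|---|---|---|
| β₀ | Normal(0, s₀²) | s₀ = 5 | weakly informative on the logit scale; covers probabilities 0.001–0.999 |
| σ_agency, σ_region, σ_species | half-Cauchy(s) | s = 2.5 | heavy-tailed, weakly informative for group SDs |
| β_f (horseshoe) | N(0, τ²λ̃²_f), λ̃²_f = c²λ²_f/(c²+τ²λ²_f) | — | sparse selection with a slab cap |
| λ_f | half-Cauchy(1) | — | local shrinkage |
| τ | half-Cauchy(τ₀) | τ₀ = p₀/((P−p₀)√n), p₀ = 5 | the global scale encodes an expected count p₀ of nonzero coefficients among P at sample size n |
| c² | Inv-Gamma(ν/2, ν s_slab²/2) | ν = 4, s_slab = 2 | Student-t(ν, 0, s_slab) slab for unshrunk coefficients |
| β_f (normal option) | Normal(0, s_β²) | s_β = 5 | non-sparse reference prior, used for calibration studies |

All hyperparameters are constructor arguments and are serialized with the
fit for provenance. Predictors must be standardized (mean 0, SD 1, sample
SD with the n−1 denominator) before fitting so the horseshoe acts on one
common scale; the fitted transform record maps prediction grids back to
original units. Standardization is computed over observation-aligned rows
(stream values repeated per fish); per-unique-stream scaling can be had by
standardizing the stream table directly before alignment.

### Collinearity screen

A greedy screen visits predictors in a declared priority order (default:
column order) and drops a predictor iff its Spearman |ρ| with any
already-retained predictor is ≥ 0.90. Every drop is logged with the
partner and the offending ρ. The screen uses |ρ| (signed screening is an
option), and after it no retained pair reaches the threshold. Which
member of a correlated pair survives is exactly the priority order —
deterministic and auditable.

## Inference

Sampling is No-U-Turn Hamiltonian Monte Carlo (slice-sampled doubling
trajectories, leapfrog integrator) written against an unconstrained
reparameterization of the joint density:

- log transforms with exact Jacobians for all scale parameters
  (σ's, τ, λ_f, c);
- non-centered random effects (effect = σ·z, z ~ N(0,1)) by default —
  hierarchical logistic models with weak groups mix poorly when centered;
  a centered option exists and is tested to give equivalent posteriors;
- horseshoe coefficients always non-centered: β_f = z_f · τλ̃_f.

Gradients are analytic. Observations sharing a (stream, agency,
ecoregion, species) cell are aggregated to binomial counts, so one
gradient evaluation costs O(#cells + #streams × #predictors) rather than
O(#fish); at the survey's structure this is a 10–100× saving.

Warmup adapts the step size by dual averaging toward a target acceptance
statistic (default 0.95) and a diagonal mass matrix from the
regularized sample variance over expanding warmup windows. Defaults: 4
chains, 1,000 warmup, 1,000 retained draws, maximum tree depth 10.
Initial points are drawn from moderately truncated prior ranges and
retried (up to 10×) if the density is non-finite; points far outside any
plausible scale (|x| > 50 on the unconstrained scale) are treated as
zero-density, which the sampler records as a divergence rather than an
arithmetic overflow. Chains are seeded by spawning independent streams
from one seed; identical inputs give bitwise-identical draws on one
platform.

Convergence is a numeric gate, not an eyeball check: split potential
scale reduction (classic variance-ratio form) ≤ 1.01 for every monitored
parameter, bulk effective sample size ≥ 400, and divergent transitions
not exceeding a tolerance of 0 by default. Failure flags the draws and
(in the CLI) aborts with a dedicated exit code unless explicitly allowed;
it never deletes them.

## Posterior summaries

- **Intervals** are equal-tailed empirical quantiles with linear
  interpolation of order statistics — stated because endpoint values at a
  few thousand draws differ across quantile rules.
- **Probability of direction (pd)** is the fraction of draws sharing the
  sign of the posterior mean; draws exactly at zero count half (the
  sign-symmetric continuous limit) and a mean of exactly zero returns 0.5.
- **Classification**: `significant` iff the 90% CI excludes zero, else
  `pd_significant` iff pd > 0.90 (strict), else `not_significant`. The
  interval and pd criteria are logically independent; the classes always
  partition the predictor set.
- **Group probability tables** summarize logit⁻¹(β₀ + effect_ℓ) per factor
  level with the other random-effect blocks plugged in at their prior mean
  of zero (the plug-in reading of the model equation), plus a
  population-average row logit⁻¹(β₀). Species are flagged as above/below
  average by whether the level's logit-scale effect interval excludes
  zero — the probability itself is always positive, so the flag must be
  read on the effect scale. A fully marginalized (integrated-over-groups)
  average is deliberately not the default.
- **Response curves** move one predictor over a grid in original units
  (mapped through the stored transform record) with all other predictors
  at their study average (0 standardized) and random effects at zero.

## Synthetic data generator

The generator draws from exactly the model the analysis assumes: MVN
stream predictors (optionally with one designed high-correlation pair to
exercise the screen), one agency and ecoregion per stream, zero-truncated
negative-binomial fish counts per stream (size 1.0 by default, matching
the heavy right skew of real survey effort), species membership per
stream from per-species Beta(1.5, 5) inclusion probabilities with
lognormal abundance weights (so species sample sizes span orders of
magnitude), and Bernoulli outcomes at the linear predictor. Everything
sampled is stored in a `GroundTruth` for recovery tests.

`study_mimic_config()` fixes the structure at the regional survey's
scale — 57 species, 7 agencies, 9 ecoregions, 1,196 streams, 46
predictors — with random-effect SDs of 1.5 (agency), 1.2 (species) and
0.3 (ecoregion) on the logit scale (agencies and species spread
occurrence probabilities over roughly two orders of magnitude; ecoregions
are tight), five nonzero coefficients (0.8, 0.6, −0.6, 0.5, −0.5)
standing in for the strongest landscape effects, and an intercept solved
by Gauss–Hermite quadrature so the *marginal* prevalence is 1.4%. The
default run scales mean per-stream effort down 20× (full scale: 149 fish
per stream) to keep integration runs desk-sized.

What the generator does **not** emulate: spatial autocorrelation beyond
the ecoregion factor, within-stream predictor variation, temporal trends
or seasonality, protocol-specific anomaly definitions, and any real
landscape covariance structure. Passing recovery tests therefore show the
pipeline is correct *under its own assumptions* — they do not certify the
model against real-data violations of those assumptions. Note also that
with only 7 agency and 9 ecoregion draws at SDs this large, a single
realization's observed prevalence and plug-in population average scatter
widely around the 1.4% marginal target; that is a property of the skewed
logit-normal design, not a calibration error.

## Numerical and design notes

- `inverse_logit` evaluates via exp(−|x|) so neither tail overflows.
- The joint log density includes all normalizing constants and matches a
  per-term textbook-density summation to 10⁻¹⁰ (tested); the sampler's
  internal target equals it plus the exact reparameterization Jacobian
  (tested to 10⁻⁸).
- Fish with a recorded aggregate DELT flag but no per-anomaly breakdown
  pass through the crosswalk untouched; the crosswalk only fills rows
  that lack the aggregate.
- Labels are matched case-sensitively after whitespace trimming;
  categorical joins are therefore deterministic.
- Missing predictor values are not imputed; streams lacking a screened
  predictor are rejected with an explicit join error listing offenders.
- Young-of-year exclusion is an upstream data-preparation responsibility;
  the readers accept pre-filtered data.
- Problem sizes in the test suite (10,000-fish recovery runs, 50 × 1,000
  coverage replicates, 500-observation grid-oracle checks) are the
  package's chosen desk-scale study conditions; they keep the full suite
  in minutes while leaving every statistical check well-powered.

## Known limitations

- The sampler is single-threaded and runs chains sequentially; very large
  cell counts (≫10⁵) or deep funnels will be slow before they are wrong.
- The divergence tolerance of 0 is strict: short runs on hard posteriors
  may be flagged even when estimates are usable; the flag is informative,
  not destructive.
- The species-specific variant refuses multi-species data rather than
  iterating species internally; loop over focal species explicitly.
- pd is reported on [0.5, 1] but is itself a Monte-Carlo estimate; at
  2,000–4,000 draws its resolution near 1 is limited by draw count.
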