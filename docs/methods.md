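# Methods

## Scope and shape

The package is an analysis pipeline, not a predictive estimator: its
stages (simulate → per-replicate estimation → meta-analytic pooling →
criterion classification → report) map onto plain functions returning
typed result objects, in the style of statistical modeling libraries
rather than an estimator API with `fit`/`predict` — grouping structure,
mixed response families, and multi-stage outputs do not reduce to a
single feature-matrix/target contract.

## Per-replicate models

One replicate is one laboratory's run of one outcome.  Three families:

* **Gaussian.**  The raw response is transformed (log(y+1) for
  immobility durations bounded by a 600 s assay ceiling, √y for
  distances bounded by a 144 cm arena) and the two-group contrast is the
  OLS slope of the treatment indicator.  Inference uses the t
  distribution on n−2 residual degrees of freedom; this matches the
  printed per-lab interval bounds of the bundled study better than a
  normal approximation.  A zero-residual-variance fit returns the
  estimate with inference flagged `degenerate` (no p, point CI).
* **Binary logit.**  Repeated binary choices per individual:
  logit P(yᵢⱼ=1) = β₀ + β₁xᵢ + uᵢ, uᵢ ~ N(0, σᵤ²).  Unscorable
  observations are dropped (they are missing completely at random under
  the generator's thinning model).
* **Proportion logit.**  Per-dish counts sⱼₜ out of mⱼₜ ≤ 3 scorable
  individuals: logit pⱼₜ = β₀ + β₁xⱼ + uⱼ + eⱼₜ with a dish intercept
  uⱼ and an observation-level random effect (OLRE) eⱼₜ ~ N(0, σₑ²)
  absorbing overdispersion.  Rows with zero trials carry no information
  and are dropped.

The treatment contrast is always non-reference minus reference on the
model scale; reference levels are declared per outcome (defaults:
control, brown, larvae).  Mixed-model inference is Wald-z.  Replicate
significance for classification is p < 0.05; a tie at exactly 0.05
counts as non-significant.

### Laplace estimation

The mixed models are estimated by maximizing the Laplace approximation
of the marginal likelihood,

  ℓ(β, θ) ≈ ℓ_pen(β, û, ê, θ) − ½ log det H(û, ê) + ½ n_re log 2π,

where (û, ê) is the joint mode of the penalized log-likelihood for
fixed (β, θ) and H its curvature in the random effects.  Because every
random term is an intercept tied to one grouping factor (plus at most
one effect per row nested in that factor), the mode is found by Newton
steps solved exactly through block elimination — the OLRE block is
diagonal, and after eliminating it the unit block is diagonal too — so
no large matrix is ever assembled and the cost per iteration is linear
in the number of rows.

The outer maximization over (β, log σᵤ, log σₑ) is deterministic
Nelder-Mead, started from a fast profile fit that maximizes the
penalized likelihood jointly over coefficients and random effects (the
familiar "inner PIRLS" shortcut).  The profile stage alone is not used
as the final answer: the log-determinant term depends on β, and
ignoring it shifts fixed effects by amounts that matter (order 0.05 on
a log-odds scale in our checks), whereas the full optimization agrees
with a 50-node adaptive Gauss-Hermite quadrature benchmark to < 1e-3 at
the cluster richness of the study designs.  Standard errors are the
numeric curvature of the Laplace log-likelihood in β at the estimated
variance components (conditional-on-θ Wald convention).

Numerical choices: log-SD search box [−6, 3] with a quadratic penalty
outside it; a variance component whose profile or final estimate falls
at the lower edge (σ < about 4e-3) is a boundary solution and is
re-fitted with the component dropped exactly — the objective is
continuous in σ at 0, and this removes the flat region on which a
simplex search can cycle.  The inner Newton uses step halving and a
1e-12 penalized-log-likelihood tolerance; outer tolerances are 1e-6
(parameters) and 1e-9 (objective), with restarts until no further
improvement.  Zero-pinned variance components reduce the fit exactly to
the IRLS GLM solution (tested to 1e-6).  Estimates diverging beyond
|β| = 25 raise a separation error advising penalized estimation.

### Auxiliary tests

* **Overdispersion**: Pearson χ² (sum of squared Pearson residuals at
  the conditional fitted values) over residual df (n − fixed −
  estimated variance components); the p-value is the upper χ² tail.
* **Rank-sum**: W counts pairs (a, b) with a > b plus half-ties — the
  Mann-Whitney convention; exact enumeration p for tie-free pooled
  n ≤ 20, otherwise normal approximation with tie and continuity
  corrections (delegated to scipy, whose conventions match exactly).
* **Spearman**: Pearson correlation of mid-ranks, t-approximation p
  (scipy).
* **Treatment-by-laboratory LRT**: the pooled model with treatment,
  laboratory and interaction fixed effects versus the model without the
  interaction, 2Δℓ on (labs − 1) df.  Gaussian outcomes use the
  closed-form ML statistic n·log(RSS_r/RSS_f); binomial families refit
  the Laplace models.  Type-I error at the default gaussian conditions
  is 0.054 over 1,000 null simulations (nominal 0.05).

## Random-effects pooling

yᵢ ~ N(μ, vᵢ + τ²) across k laboratories.  τ² by REML (bounded Brent on
[0, upper], tolerance 1e-10, boundary snapped to exactly 0 when the
restricted likelihood is maximized there) or by the DerSimonian-Laird
moment formula max(0, (Q − (k−1))/C).  μ is the weighted mean with
weights 1/(vᵢ + τ²), se(μ) = (Σwᵢ)^{−1/2}, CI and p by Wald-z with no
small-sample adjustment — this matches the printed pooled intervals,
whose half-widths are 1.96·SE.

**Variance interpretation.**  Reconstructing the bundled study's pooled
rows succeeds only when the printed per-lab SE column enters directly
as the sampling variance vᵢ (all four outcomes match to ±0.03 under
`se_as_variance`; under vᵢ = SEᵢ² the substrate-choice pooled SE would
be ≈ 0.11 against a printed 0.26).  Whether the original analysis
intended that or the column is mislabeled cannot be decided from the
printed numbers alone, so both modes are explicit flags: reproduction
work uses `se_as_variance`, new analyses default to the statistically
standard `se_squared`, and every report names the mode.

**Overall significance** is the pooled 95% CI excluding zero, evaluated
at full precision when the pooled row is computed in-pipeline.  For
printed inputs the comparison is sign-based with IEEE signed zeros
honored: a bound stored as −0.00 counts as below zero (a negative value
rounded for printing), +0.00 as touching zero.  This is a no-op for
full-precision values.

## Classification

Per replicate: significance congruence (same status as the overall
result and, when both significant, same sign; opposite-sign
significance counts as incongruent), coverage (the replicate's CI
contains μ; closed interval, so a bound exactly at μ covers), accuracy
(both).  Aggregation scopes: all replicates, per outcome (cell fraction
= check marks over labs × 3 criteria), and the subset of outcomes whose
overall effect is significant.  By construction the accuracy proportion
never exceeds either component, which the suite asserts both row-wise
and in aggregate.

## Synthetic data generator

Each archetype simulates on the model (link) scale and back-transforms:
lab intercepts αⱼ = α + N(0, σ_lab²), lab slopes βⱼ = β + N(0,
σ_slope²) — σ_slope > 0 is what a treatment-by-laboratory interaction
test should detect.  A single seed spawns one child stream per
laboratory, so adding a laboratory never changes existing labs' data
and identical configurations are bit-reproducible.

* Gaussian: y′ ~ N(αⱼ + βⱼx, σ²), raw response = inverse transform
  clipped to [0, ceiling]; truncated values are retained (capped assay
  durations), not flagged.
* Binary: per-individual intercepts, Bernoulli responses over T
  scheduled time points, each independently scorable with the
  availability probability; unscorable rows keep their slot with a
  missing response.
* Dish: trials ~ Binomial(3, availability of that treatment level) per
  time point, successes ~ Binomial(trials, p) with dish intercept and a
  fresh observation-level normal effect per row.

Default conditions follow the three-lab study designs: 3 labs; 30
individuals per group (gaussian, effect −1.67 on the log scale, 600 s
ceiling); 31 per group × 50 scheduled choices with 15.1% scorability
(binary, effect 0.15 log-odds); 36 dishes per group × 14 time points of
3 individuals with adult availability 0.334 (dish, effect −0.41
log-odds).  Between-lab SDs are illustrative — the study reports no
variance components — with moderate intercept variation and
σ_slope = 0 by default (perfect reproducibility); the bundled
`pci_heterogeneous` scenario sets σ_slope = 1.2, at which typically
about one lab in three misses significance.  The gaussian default
places the control mean (α = 3.5, residual SD 0.8 on the log scale)
far enough below the ceiling that truncation rarely binds, so the
analysis model is correctly specified and parameter recovery is clean;
pushing α toward the ceiling reproduces the attenuation a capped assay
induces.  The residual SD was chosen so the per-lab standard error at
n = 30 per group (≈ 0.21) matches the tightest printed per-lab SE.

What the generator does *not* emulate: biology (molting, cannibalism,
diel rhythms), serial correlation within individuals beyond the random
intercept, non-random missingness (availability is independent
Bernoulli thinning; the study only reports marginal scorability rates),
or lab differences in protocol execution.  Passing recovery tests
therefore show the estimators are correct under the stated generative
model, not that real data meet its assumptions.

## Verification design

Every nontrivial computation has an independent check: the Laplace fits
against an adaptive Gauss-Hermite oracle (and the degenerate path
against IRLS GLM solutions), REML against dense grid search, DL against
a hand-worked two-study case and a loop-written duplicate, the rank-sum
p against brute-force enumeration of assignments, the gaussian LRT
against its closed RSS form, and the full classification grid against
the published check-mark table.  Oracle comparisons use datasets with
the study designs' cluster sizes (50 choices per individual, 14
time points of 3 per dish); with much sparser clusters (e.g., 10
Bernoulli observations per unit) the genuine Laplace-vs-quadrature
approximation gap exceeds the comparison tolerance and no longer
measures implementation correctness.

Simulation-based checks use 200 replicates (estimator bias, CI
coverage, dispersion calibration) or 1,000 (LRT type-I error) at the
default scenario sizes; these sizes keep Monte-Carlo error a few times
smaller than the asserted tolerances.

## Known limitations

* Single grouping factor plus optional OLRE; no crossed or nested
  multi-factor random effects, no random slopes in estimation (random
  slopes exist only in the generator, as the between-lab
  heterogeneity).
* Wald/likelihood asymptotics throughout: no Satterthwaite or
  Kenward-Roger degrees of freedom, no Knapp-Hartung adjustment in the
  pooling (k = 3 intervals are therefore anti-conservative in general —
  retained to match the published computation).
* The Laplace approximation is known to be biased for very sparse
  binary clusters; with the bundled designs' cluster sizes the bias is
  negligible, and the quadrature oracle in the test suite is the
  reference for anything sparser.
* The meta-analysis is univariate per outcome; outcomes are pooled and
  classified independently even when measured on the same animals.
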