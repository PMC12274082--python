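# Methods

This note documents the statistical procedures implemented in `longmec`,
the assumptions they rest on, the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does not
emulate.

## Outcome model and correction

The marginal model is `g(E[Y_ij]) = X_ij' β` with design
`X_ij = (1, h_ij, t_ij, h_ij t_ij, W_ij')'`, where `h_ij` summarizes the
exposure history up to visit j.  Two functionals are provided:

- **Cumulative average** `s(t_j) = Σ_{k<j} (t_{k+1}−t_k) c(t_k) / (t_j−t_1)`
  with the convention `s(t_1) = c(t_1)` (the formula is 0/0 at the first
  visit).  The sum runs to j−1 with left-endpoint interval weights exactly
  as written; no trapezoidal variant is offered.
- **Moving average** over the half-open calendar window `(t_j − w, t_j]`,
  interval-weighted, with the current visit carrying the preceding gap so
  an equally spaced series yields the arithmetic mean of the in-window
  values.  The left-most interval is truncated at the window boundary.
  Missing values are dropped with their weights; a window containing no
  observed value yields a missing entry.  (How missing months should enter
  a 12-month moving average is a contract of this package, not a settled
  convention.)

Because `h` depends on the unobservable true exposures, the corrected
estimator replaces each `c(t_k)` by the calibration prediction
`ĉ(t_k) = α̂0 + α̂1 C + α̂2 t + α̂3 C t + W'α̂4` and fits the GEE on the
estimated history `ŝ`.  Validity rests on four assumptions:

1. **Surrogacy** — given the true exposure history and covariates, the
   surrogate history carries no extra information about the outcome;
2. **Localized error** — `E[c(t)|history] = E[c(t)|C(t), t, W(t)]`,
   testable via the sequential-ANOVA F test in `localized_error_test`
   (base model: the calibration design; added regressor: the mean of prior
   surrogates, or the most recent one with `history="last"`);
3. **Small effect / small error** — the first-order Taylor expansion of
   `g^{-1}` is adequate; gauged by the diagnostic
   `β̂' V̂ar(X|C̃,t̃,W̃) β̂`, which the package computes as
   `σ̂²_ε Σ_k w_jk² (β̂1 + β̂3 t_j)²` averaged over visits (only the history
   columns of X are random given the observed data; calibration residuals
   are taken independent across visits — the residual covariance entering
   the cumulative average is not identified and this choice is flagged in
   the API docs).  Values above 0.4 trigger a warning;
4. **Transportability** (MS/EVS) — the calibration model estimated
   externally applies in the main study.

## Estimation

The calibration model is fitted by an identity-link GEE over validation
individuals (working correlation selectable); with one observed
true-exposure visit per individual this collapses to pooled OLS, which the
implementation reproduces exactly.  The residual variance `σ̂²_ε` is the
residual mean square pooled over visits — per-visit variances are not
separately identified by the designs this package targets.  The C×t
interaction is included by default; omitting it while the outcome model
keeps `h×t` logs a misspecification warning, since an exposure-by-time
interaction in the outcome model requires the same interaction in the
calibration model for the correction to be valid.

The outcome GEE is solved by Fisher scoring with logit / identity / log
links and independence / exchangeable / AR(1) working correlation, the
correlation parameter re-estimated each iteration by moments from Pearson
residuals (lag-1 products for AR(1), all within-cluster pairs for
exchangeable; clipped to (−0.99, 0.99)).  AR(1) is indexed by visit order
(ρ^|j−k|); a gap-based variant ρ^|t_j−t_k| is available behind a flag.
Initialization is the independence GLM fit; convergence is declared when
the maximum relative coefficient change falls below 1e-8 (at most 100
iterations); binary outcomes use variance μ(1−μ) with no scale factor,
identity/log links estimate a moment dispersion.  Clusters of equal size
are processed as stacked 3-d arrays, which keeps a 5000-cluster fit around
50 ms and makes hundreds of simulation replicates cheap.

Under MS/IVS the default ("plug-in") corrected analysis imputes `ĉ` for
everyone in MS ∪ IVS; `fit_corrected_true_ivs` substitutes observed true
exposures in the IVS (histories built from the merged series, predicted
values filling unobserved visits).  `fit_ivs_only` analyzes the IVS alone:
with complete true-exposure series, a GEE on the true history; with a
single measurement, an independent logistic regression treating that
measurement as the cumulative average at its visit (each individual
contributes the row at its unique observed visit, or the most recent
observed one).  The IVW estimator combines the corrected main-study-only
estimate with the IVS-only estimate by **coefficient-wise**
inverse-variance weights; this is the form whose operating characteristics
match the combined estimator's published behaviour, because the full
matrix-weighted version (available via `method="matrix"`) lets
off-diagonal covariance terms place substantial weight on the
misspecified IVS-only estimate.  The IVS-only variance entering the
weights is the classical model-based covariance, as appropriate for an
independent-row regression.

## Variance estimation

`Var(θ̂) = B⁻¹ A B⁻¹'` for the stacked estimating function
`ψ = (ψ_α', ψ_β')'`.  The bread is block lower-triangular (the calibration
equation never involves β); the cross block `∂ψ_β/∂α` is computed
analytically by the chain rule through `ĉ → ŝ → X̂ → μ`, holding the
working covariance fixed at its fitted value, with three terms: the design
term `(∂X'/∂α) Δ V⁻¹ r`, the curvature term `X' diag(μ'' ∂η/∂α) V⁻¹ r`,
and the mean term `−X' Δ V⁻¹ Δ (∂η/∂α)`.  A central-difference version
(step `1e-6·(1+|α_k|)`) serves as an internal oracle and the two agree to
~1e-6 in the tests.  The meat is the empirical outer product of
per-individual stacked scores: under MS/EVS no individual contributes both
components (block-diagonal meat); under MS/IVS the validation individuals
contribute both and the cross products are retained.  No small-sample
correction is applied by default (an optional `N/(N−p)` factor exists).
A stratified cluster bootstrap (`bootstrap_variance`) provides an
independent check; on a generated dataset of 1000 main-study and 300
validation individuals the stacked and 500-resample bootstrap standard
errors agree within about 5%.

## The synthetic-data generator

`simulate.generate_dataset` emulates a five-wave cohort with staggered
entry: `t_i1 ~ U(0,1)`, unit spacing; `(C, W)` jointly multivariate normal
with AR(1) blocks (variance 1, correlations 0.6 and 0.2) and same-visit
cross-covariance 0.4; true exposure from the linear calibration model with
`α = (1.2, 0.6, 0.5, 0.4, 0.3)` and homoscedastic normal residuals; binary
outcomes from the marginal logit model on the true cumulative average with
serial dependence.  Default coefficient vectors give average outcome
prevalences near 15% (`β3 = −log 1.1`) and 5% (`β3 = −log 1.5`).

Open choices resolved here:

- **Residual variance.**  Solved so the *visit-averaged Pearson
  correlation* between `c` and `C` hits the target (0.90 by default).  The
  solver draws one fixed-seed Monte Carlo sample of the noiseless design
  and root-finds in closed form over it, so the answer is deterministic
  and the correlation is monotone decreasing in `σ²_ε` (targets above the
  zero-noise correlation raise a domain error).  Under this definition the
  solutions are ≈0.40 (target 0.90) and ≈1.76 (target 0.75).  Correlation
  between longitudinal processes admits several conventions (pooled,
  per-visit, partial given time); they give materially different variance
  scales, and the visit-averaged form was chosen as the cleanest
  population analogue of "the correlation between c(t_ij) and C(t_ij)".
  Alternatively the variance can be tuned to a target value of the Taylor
  diagnostic (`target_diagnostic`), for which the diagnostic is linear in
  `σ²_ε` and the solution is exact.
- **Correlated binary outcomes.**  A Gaussian copula: latent AR(1)
  standard normals thresholded at `Φ⁻¹(μ_ij)`, so the marginals hold
  exactly.  The latent correlation is calibrated by root-finding (bivariate
  normal orthant probabilities over a sample of adjacent-visit mean pairs)
  so the *conditional* binary lag-1 correlation equals 0.1; the achieved
  value is verified within ±0.02 in the tests.  Matching on the latent
  scale instead is available (`binary_corr_scale="latent"`).
- **Single-measurement validation.**  The observed visit is the rank of
  the first entry of an independent uniform 5-vector (ties broken by
  position), uniform over visits in distribution.
- **Replicate seeding.**  Per-replicate seeds are spawned from the master
  seed with `SeedSequence`, so summaries are bit-identical regardless of
  parallel scheduling.

What the generator does **not** emulate: unequal cluster sizes or dropout,
missing surrogate measurements, heteroscedastic or serially correlated
calibration residuals, non-normal exposures, and covariate-dependent
observation times.  Passing tests therefore demonstrate correctness of the
estimators under a clean longitudinal design, not robustness to those
real-data complications.

## Problem sizes and known limitations

The test suite and the acceptance script run the Monte Carlo studies at
200–500 replicates with `n1` of 2000–5000 and `n2` of 500 — sizes chosen
so the whole suite completes in a few minutes while keeping the Monte
Carlo standard error of a relative-bias estimate near one percentage
point.  The correction is first-order: its residual bias grows with
`β' Var(X|·) β`, and in the strong-interaction settings the package's own
acceptance runs show the corrected estimator's relative bias rising to
several percent at diagnostic 0.4 and ~15% at 0.9 — consistent with the
0.4 guideline for trusting the approximation.  Higher-order Taylor
corrections and likelihood-based alternatives are out of scope, as are
GEE2 / unstructured working correlation, weighted GEE for informative
dropout, and survival-format inputs.  The calibration and outcome models
must share one consistent time column.
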