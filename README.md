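# longmec

Measurement-error correction for longitudinal regression when the exposure
of interest is a **function of a mismeasured exposure history**.

## The problem

Environmental and nutritional epidemiology often relates a longitudinal
health outcome to a summary of past exposure — for example, the cumulative
average of air-pollution levels up to each questionnaire cycle.  The
individual exposure measurements entering that history (say, PM2.5 predicted
from a spatiotemporal model at a person's address) are error-prone
surrogates `C(t)` of the true personal exposure `c(t)`, and plugging the
surrogate history into a GEE analysis biases the estimated exposure effects.
When a validation study measures the gold standard `c` alongside `C` —
either in an external sample (MS/EVS design) or in a subset of the cohort
itself (MS/IVS design) — the bias can be removed by regression calibration.

`longmec` implements this correction for outcomes linked to the linear
predictor through a general link function (logistic regression for binary
outcomes being the key case), together with a stacked M-estimation variance
that propagates the calibration uncertainty, alternative estimators for the
internal-validation design, diagnostics for the method's assumptions, and a
simulation engine for studying the operating characteristics.

## The model

Marginal outcome model for individual `i` at visit time `t_ij`:

    g(E[Y_i(t_ij)]) = b0 + b1*h(c̃_i(t_ij)) + b2*t_ij
                      + b3*h(c̃_i(t_ij))*t_ij + W_i'(t_ij)*b4,

where `h(·)` is an exposure-history functional — the cumulative average
`s(t_j) = sum_{k<j} (t_{k+1}-t_k) c(t_k) / (t_j - t_1)` by default, a
calendar-window moving average optionally — and `b3`, the history-by-time
interaction, measures how the outcome trajectory changes with cumulative
exposure.  The calibration (measurement-error) model fitted in the
validation study is linear:

    E[c(t) | C(t), t, W(t)] = a0 + a1*C(t) + a2*t + a3*C(t)*t + W'(t)*a4.

The corrected estimator predicts `ĉ` at every main-study visit, builds the
estimated history `ŝ`, and solves the outcome GEE with `ŝ` in place of the
unobservable `s`.  This is justified by a first-order Taylor argument that
requires the quadratic form `b' Var(X | C̃, t̃, W̃) b` to be small
(guideline: below 0.4); the package computes this diagnostic, and a
sequential-ANOVA test of the *localized error* assumption (that only the
same-visit `(C, t, W)` predicts `c`).

Variances come from the stacked sandwich `Var(θ̂) = B⁻¹ A B⁻¹'` for the
joint estimating function of `θ = (α', β')'`, so the reported standard
errors for `β̂` include the cost of estimating `α̂`.  For the MS/IVS design
the package also provides the variant that uses observed true exposures in
the validation subset, the IVS-only estimator, and their inverse-variance-
weighted (IVW) combination.

## Worked example

Generate a synthetic MS/EVS study (2000 cohort members, 500 external
validation participants, five visits, true-vs-surrogate correlation 0.90)
and compare the uncorrected and corrected analyses:

```python
import numpy as np
from longmec import (SimulationConfig, generate_dataset, resolve_config,
                     fit_calibration, fit_naive, fit_corrected)

config = SimulationConfig(
    n1=2000, n2=500, target_cor=0.90,
    beta=(-3.0, np.log(1.2), 0.5, -np.log(1.1), np.log(1.2)))
main, validation = generate_dataset(config, seed=42,
                                    resolved=resolve_config(config))

calib = fit_calibration(validation, corr="ar1")
naive = fit_naive(main, corr="ar1")
corrected = fit_corrected(main, calib, corr="ar1", design="ms_evs")
print(corrected.summary().round(4))
```

Output:

```
calibration alpha: [1.194 0.604 0.505 0.391 0.361]  sigma2_eps: 0.412

naive fit (h_x_t):      estimate -0.1276   se 0.0234
corrected fit:
       estimate      se  ci_lower  ci_upper
const   -3.1256  0.1346   -3.3895   -2.8618
h        0.2143  0.0708    0.0756    0.3530
t        0.5611  0.0425    0.4777    0.6445
h_x_t   -0.1125  0.0207   -0.1531   -0.0719
W        0.1587  0.0306    0.0988    0.2187

true beta: [-3.  0.1823  0.5  -0.0953  0.1823]   diagnostic: 0.0053
```

The calibration coefficients recover the generating values
`(1.2, 0.6, 0.5, 0.4, 0.3)`; the naive interaction estimate (−0.128) is
biased away from the truth (−0.095) while the corrected one (−0.113, SE
from the stacked sandwich) moves back toward it; the Taylor diagnostic
0.005 is far below the 0.4 guideline, so the first-order correction is
trustworthy here.  Averaged over hundreds of replicates (see below) the
naive bias is about +25% and the corrected bias under 1%.

A command-line interface mirrors the library:

```sh
longmec calibrate data.csv --column-map map.yaml --out results/
longmec fit data.csv --estimator corrected --corr ar1 --out results/
longmec simulate --config sim.yaml --reps 500 --seed 1 --out simdir/
longmec diagnose data.csv --out results/
```

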