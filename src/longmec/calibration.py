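"""Measurement-error (calibration) model: fit, predict, and diagnostics.

The calibration model regresses the gold-standard exposure c observed in the
validation study on the same-visit surrogate, time, their interaction, and
the error-free covariates:

    c = alpha0 + alpha1*C + alpha2*t + alpha3*C*t + W'alpha4 + eps.

With one true-exposure visit per individual this is ordinary least squares;
with repeated true measurements it is an identity-link GEE with a chosen
working correlation.  Predicted exposures c_hat = E[c | C, t, W] transported
to the main study drive the regression-calibration correction.

The localized-error diagnostic checks that, given the same-visit (C, t, W),
earlier surrogate history adds no information about c (a nested-model F
test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import gee
from .history import CALIBRATED
from .panel import ID, SURROGATE, TIME, TRUE, Panel

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "predict_exposure",
    "localized_error_test",
    "InsufficientHistoryError",
]

log = logging.getLogger(__name__)


class InsufficientHistoryError(ValueError):
    """No validation visit has any prior surrogate history."""


def calibration_design(df: pd.DataFrame, covariates: tuple[str, ...],
                       include_interaction: bool) -> tuple[np.ndarray, list[str]]:
    """Design matrix (1, C, t, [C*t], W...) for given long-format rows."""
    C = df[SURROGATE].to_numpy(dtype=float)
    t = df[TIME].to_numpy(dtype=float)
    cols = [np.ones(len(df)), C, t]
    names = ["const", "C", "t"]
    if include_interaction:
        cols.append(C * t)
        names.append("C_x_t")
    for w in covariates:
        cols.append(df[w].to_numpy(dtype=float))
        names.append(w)
    return np.column_stack(cols), names


@dataclass
class CalibrationModel:
    """Fitted calibration model with stacked-sandwich ingredients."""

    alpha: np.ndarray
    sigma2_eps: float
    corr: gee.WorkingCorrelation
    rho: float
    cov_robust: np.ndarray
    bread: np.ndarray             # sum_i Z_i V_i^{-1} Z_i'
    cluster_scores: np.ndarray    # (ncl, p) psi_i^alpha at alpha_hat
    cluster_ids: np.ndarray       # individual id per score row
    design_names: list[str]
    covariates: tuple[str, ...]
    include_interaction: bool
    n_individuals: int
    n_obs: int

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def design(self, df: pd.DataFrame) -> np.ndarray:
        for w in self.covariates:
            if w not in df.columns:
                raise KeyError(
                    f"panel lacks calibration covariate {w!r}: schema mismatch")
        Z, _ = calibration_design(df, self.covariates, self.include_interaction)
        return Z

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.design(df) @ self.alpha


def fit_calibration(validation: Panel, corr="independence",
                    include_interaction: bool = True) -> CalibrationModel:
    """Fit the calibration model in the validation study.

    Visits with the true exposure missing are excluded (only observed
    occasions contribute to the estimating function).  With at most one
    observed visit per individual the fit coincides with pooled OLS.
    """
    corr = gee.get_corr(corr)
    df = validation.data
    obs = df[df[TRUE].notna()]
    if len(obs) == 0:
        raise ValueError("validation panel has no observed true exposures")
    Z, names = calibration_design(obs, validation.covariates, include_interaction)
    p = Z.shape[1]
    if len(obs) < p + 1:
        raise ValueError(f"too few validation observations ({len(obs)} < {p + 1})")
    c = obs[TRUE].to_numpy(dtype=float)
    groups = obs[ID].to_numpy()
    sizes = pd.Series(groups).groupby(pd.Series(groups)).size()
    eff_corr = corr
    if corr.structure != "independence" and (sizes < 2).all():
        # single observed visit per individual: the GEE is exactly OLS
        eff_corr = gee.WorkingCorrelation("independence")
    fit = gee.fit_gee(Z, c, groups, link="identity", corr=eff_corr,
                      times=obs[TIME].to_numpy(dtype=float),
                      column_names=names)
    resid = c - Z @ fit.beta
    sigma2 = float(resid @ resid) / max(len(obs) - p, 1)
    ids = obs[ID].drop_duplicates().to_numpy()
    return CalibrationModel(
        alpha=fit.beta, sigma2_eps=sigma2, corr=eff_corr, rho=fit.rho,
        cov_robust=fit.cov_robust, bread=fit.bread,
        cluster_scores=fit.cluster_scores, cluster_ids=ids,
        design_names=names, covariates=validation.covariates,
        include_interaction=include_interaction,
        n_individuals=fit.n_clusters, n_obs=fit.n_obs,
    )


def predict_exposure(model: CalibrationModel, panel: Panel) -> Panel:
    """Append the predicted exposure column ``c_hat`` to a panel."""
    return panel.with_column(CALIBRATED, model.predict(panel.data))


def localized_error_test(validation: Panel, history: str = "mean",
                         include_interaction: bool = True):
    """Sequential-ANOVA test of the localized-error assumption.

    Regresses the observed true exposure on the same-visit calibration design
    with and without a summary of the *prior* surrogate exposures (their mean
    by default, or the most recent with ``history="last"``); returns the
    nested-model ``(F, p)``.  A small p-value flags that earlier surrogate
    history predicts the current true exposure, violating the assumption.
    """
    if history not in ("mean", "last"):
        raise ValueError(f"unknown history summary {history!r}")
    df = validation.data
    rows = []
    prior = []
    for _, grp in df.groupby(ID, sort=False):
        C = grp[SURROGATE].to_numpy(dtype=float)
        cobs = grp[TRUE].notna().to_numpy()
        for j in range(len(grp)):
            if j == 0 or not cobs[j]:
                continue
            rows.append(grp.index[j])
            prior.append(C[:j].mean() if history == "mean" else C[j - 1])
    if not rows:
        raise InsufficientHistoryError(
            "no validation visit has both an observed true exposure and "
            "prior surrogate history")
    sub = df.loc[rows]
    Z, _ = calibration_design(sub, validation.covariates, include_interaction)
    c = sub[TRUE].to_numpy(dtype=float)
    base = sm.OLS(c, Z).fit()
    full = sm.OLS(c, np.column_stack([Z, prior])).fit()
    fstat, pval, _ = full.compare_f_test(base)
    return float(fstat), float(pval)
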