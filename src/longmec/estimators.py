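"""Outcome-model estimators for the main-study / validation-study designs.

The marginal outcome model is

    g(E[Y(t)]) = beta0 + beta1*h(t) + beta2*t + beta3*h(t)*t + W'beta4,

where h is an exposure-history functional (cumulative average by default) of
the *true* point exposures.  Estimators provided:

- ``fit_naive``: plugs in the surrogate history (measurement error ignored);
  robust GEE sandwich standard errors.
- ``fit_corrected``: regression calibration — predicts c_hat = E[c|C,t,W]
  from the fitted calibration model at every analysis visit, builds the
  estimated history, and fits the GEE; standard errors from the stacked
  sandwich that propagates calibration uncertainty.
- ``fit_corrected_true_ivs``: MS/IVS variant that substitutes observed true
  exposures in the internal validation subset.
- ``fit_ivs_only``: analysis of the IVS alone (single-measurement rule:
  each individual's observed true exposure treated as the cumulative
  average at its visit, independent logistic regression).
- ``combine_ivw``: inverse-variance-weighted combination of the corrected
  main-study estimate and the IVS-only estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gee
from .calibration import CalibrationModel
from .history import (HistoryFunctionSpec, batched_cumavg_weights,
                      cumavg_by_cluster)
from .panel import ID, OUTCOME, SURROGATE, TIME, TRUE, Panel
from .sandwich import (H_COL, HT_COL, CrossPieces, cross_block_analytic,
                       stacked_sandwich)

__all__ = [
    "CorrectionResult",
    "fit_naive",
    "fit_corrected",
    "fit_corrected_true_ivs",
    "fit_ivs_only",
    "combine_ivw",
    "approximation_diagnostic",
]

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # nominal 95% normal quantile


@dataclass
class CorrectionResult:
    """Point estimates, covariance, and diagnostics for one estimator."""

    estimator: str
    design: str | None
    beta: np.ndarray
    cov_beta: np.ndarray
    column_names: tuple[str, ...]
    rho: float
    converged: bool
    n_iter: int
    n_main: int
    n_validation: int = 0
    alpha: np.ndarray | None = None
    cov_theta: np.ndarray | None = None
    diagnostic: float | None = None
    fit: gee.GeeFit | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def ci(self) -> np.ndarray:
        """(p, 2) array of normal 95% confidence limits."""
        half = Z95 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame({
            "estimate": self.beta, "se": self.se,
            "ci_lower": ci[:, 0], "ci_upper": ci[:, 1],
        }, index=list(self.column_names))


def _outcome_design(df: pd.DataFrame, h: np.ndarray,
                    covariates: tuple[str, ...]):
    t = df[TIME].to_numpy(dtype=float)
    cols = [np.ones(len(df)), h, t, h * t]
    names = ["const", "h", "t", "h_x_t"]
    for w in covariates:
        cols.append(df[w].to_numpy(dtype=float))
        names.append(w)
    return np.column_stack(cols), names


def _history(df: pd.DataFrame, values: np.ndarray,
             spec: HistoryFunctionSpec) -> np.ndarray:
    if spec.kind != "cumulative_average":
        from .history import moving_average
        out = np.empty(len(df))
        for _, idx in df.groupby(ID, sort=False).indices.items():
            out[idx] = moving_average(
                df[TIME].to_numpy(dtype=float)[idx], values[idx], spec.window)
        return out
    return cumavg_by_cluster(df[ID].to_numpy(),
                             df[TIME].to_numpy(dtype=float), values)


def _cluster_ids(fit: gee.GeeFit, ids: np.ndarray) -> np.ndarray:
    """Individual id per cluster, in the fit's internal cluster order."""
    out = np.empty(fit.n_clusters, dtype=object)
    for b in fit._batches:
        out[b.cluster_pos] = ids[b.idx[:, 0]]
    return out


def fit_naive(main: Panel, h_spec: HistoryFunctionSpec | None = None,
              link="logit", corr="ar1") -> CorrectionResult:
    """GEE of the outcome on the surrogate exposure history (no correction)."""
    h_spec = h_spec or HistoryFunctionSpec()
    df = main.data
    h = _history(df, df[SURROGATE].to_numpy(dtype=float), h_spec)
    X, names = _outcome_design(df, h, main.covariates)
    fit = gee.fit_gee(X, df[OUTCOME].to_numpy(dtype=float),
                      df[ID].to_numpy(), link=link, corr=corr,
                      times=df[TIME].to_numpy(dtype=float),
                      column_names=names)
    return CorrectionResult(
        estimator="naive", design=None, beta=fit.beta,
        cov_beta=fit.cov_robust, column_names=tuple(names), rho=fit.rho,
        converged=fit.converged, n_iter=fit.n_iter,
        n_main=fit.n_clusters, fit=fit)


def _corrected_impl(analysis_df: pd.DataFrame, covariates, calib,
                    h_spec, link, corr, design, use_true,
                    n_validation) -> CorrectionResult:
    chat = calib.predict(analysis_df)
    c_obs = analysis_df[TRUE].notna().to_numpy() if TRUE in analysis_df else \
        np.zeros(len(analysis_df), dtype=bool)
    if use_true and c_obs.any():
        mask = (~c_obs).astype(float)
        fixed = np.where(c_obs, analysis_df[TRUE].to_numpy(dtype=float), 0.0)
        series = mask * chat + fixed
    else:
        mask = np.ones(len(analysis_df))
        fixed = np.zeros(len(analysis_df))
        series = chat
    h = _history(analysis_df, series, h_spec)
    X, names = _outcome_design(analysis_df, h, covariates)
    if "h_x_t" in names and not calib.include_interaction:
        log.warning(
            "outcome model includes an exposure-by-time interaction but the "
            "calibration model omits C x t: correction may be misspecified")
    ids = analysis_df[ID].to_numpy()
    times = analysis_df[TIME].to_numpy(dtype=float)
    fit = gee.fit_gee(X, analysis_df[OUTCOME].to_numpy(dtype=float), ids,
                      link=link, corr=corr, times=times, column_names=names)
    if h_spec.kind == "cumulative_average":
        Z = calib.design(analysis_df)
        pieces = []
        for b in fit._batches:
            pieces.append({
                "Z": Z[b.idx], "Ws": batched_cumavg_weights(times[b.idx]),
                "mask": mask[b.idx], "fixed": fixed[b.idx],
                "times": times[b.idx],
            })
        cross = CrossPieces(pieces, p_alpha=len(calib.alpha))
        Bba = cross_block_analytic(fit, cross, fit.beta)
        cov_theta = stacked_sandwich(
            calib, fit, _cluster_ids(fit, ids), Bba, design)
        pa = len(calib.alpha)
        cov_beta = cov_theta[pa:, pa:]
        diag = _diagnostic_value(fit.beta, calib.sigma2_eps, pieces)
    else:
        # moving-average history: calibration uncertainty not propagated
        log.warning("stacked sandwich implemented for the cumulative average; "
                    "reporting robust (non-stacked) covariance")
        cov_theta, cov_beta, diag = None, fit.cov_robust, None
    res = CorrectionResult(
        estimator="corrected_true" if use_true else "corrected",
        design=design, beta=fit.beta, cov_beta=cov_beta,
        column_names=tuple(names), rho=fit.rho, converged=fit.converged,
        n_iter=fit.n_iter,
        n_main=fit.n_clusters - (n_validation if design == "ms_ivs" else 0),
        n_validation=n_validation, alpha=calib.alpha, cov_theta=cov_theta,
        diagnostic=diag, fit=fit)
    if diag is not None and diag > 0.4:
        log.warning("approximation diagnostic beta'Var(X|.)beta = %.3f "
                    "exceeds 0.4: first-order correction may be inadequate",
                    diag)
    return res


def fit_corrected(main: Panel, calib: CalibrationModel,
                  h_spec: HistoryFunctionSpec | None = None,
                  link="logit", corr="ar1", design: str = "ms_evs",
                  validation: Panel | None = None) -> CorrectionResult:
    """Regression-calibration corrected GEE with stacked sandwich variance.

    Under MS/EVS the analysis set is the main study (N = n1); under MS/IVS
    it is the union of main study and internal validation study
    (N = n1 + n2), with c_hat imputed at every visit for everyone.
    """
    h_spec = h_spec or HistoryFunctionSpec()
    if design not in ("ms_evs", "ms_ivs"):
        raise ValueError(f"unknown design {design!r}")
    if design == "ms_ivs":
        if validation is None:
            raise ValueError("MS/IVS design requires the validation panel")
        analysis_df = pd.concat([main.data, validation.data],
                                ignore_index=True)
        analysis_df = analysis_df.sort_values([ID, TIME],
                                              kind="mergesort").reset_index(drop=True)
        n_val = validation.n_individuals
    else:
        analysis_df = main.data
        n_val = calib.n_individuals
    return _corrected_impl(analysis_df, main.covariates, calib, h_spec,
                           link, corr, design, use_true=False,
                           n_validation=n_val)


def fit_corrected_true_ivs(main: Panel, validation: Panel,
                           calib: CalibrationModel,
                           h_spec: HistoryFunctionSpec | None = None,
                           link="logit", corr="ar1",
                           design: str = "ms_ivs") -> CorrectionResult:
    """MS/IVS corrected fit using observed true exposures where available."""
    if design != "ms_ivs":
        raise ValueError("the true-exposure-in-IVS variant requires MS/IVS")
    h_spec = h_spec or HistoryFunctionSpec()
    analysis_df = pd.concat([main.data, validation.data], ignore_index=True)
    analysis_df = analysis_df.sort_values([ID, TIME],
                                          kind="mergesort").reset_index(drop=True)
    return _corrected_impl(analysis_df, main.covariates, calib, h_spec,
                           link, corr, design, use_true=True,
                           n_validation=validation.n_individuals)


def fit_ivs_only(ivs: Panel, h_spec: HistoryFunctionSpec | None = None,
                 link="logit", corr="ar1") -> gee.GeeFit:
    """Outcome analysis of the internal validation study alone.

    With complete true-exposure series, a GEE on the true exposure history.
    With incomplete series, one row per individual at the selected
    observed-c visit (the unique one, else the most recent), with the single
    true exposure standing in for the cumulative average — an independent
    logistic (or link-appropriate) regression.
    """
    h_spec = h_spec or HistoryFunctionSpec()
    df = ivs.data
    if df[OUTCOME].isna().any():
        raise ValueError("IVS-only analysis requires outcomes on all rows")
    complete = df[TRUE].notna().all()
    if complete:
        h = _history(df, df[TRUE].to_numpy(dtype=float), h_spec)
        X, names = _outcome_design(df, h, ivs.covariates)
        return gee.fit_gee(X, df[OUTCOME].to_numpy(dtype=float),
                           df[ID].to_numpy(), link=link, corr=corr,
                           times=df[TIME].to_numpy(dtype=float),
                           column_names=names)
    rows = []
    for _, grp in df.groupby(ID, sort=False):
        obs = grp.index[grp[TRUE].notna()]
        if len(obs) == 0:
            continue
        rows.append(obs[-1])  # unique visit, or the most recent observed
    if not rows:
        raise ValueError("no IVS individual has an observed true exposure")
    sub = df.loc[rows]
    X, names = _outcome_design(sub, sub[TRUE].to_numpy(dtype=float),
                               ivs.covariates)
    return gee.fit_gee(X, sub[OUTCOME].to_numpy(dtype=float),
                       sub[ID].to_numpy(), link=link, corr="independence",
                       times=sub[TIME].to_numpy(dtype=float),
                       column_names=names)


def _vcov_of(fit) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fit, CorrectionResult):
        return fit.beta, fit.cov_beta
    # GeeFit: model-based covariance for an independent-row regression,
    # cluster-robust otherwise
    if fit.n_clusters == fit.n_obs:
        return fit.beta, fit.cov_naive
    return fit.beta, fit.cov_robust


def combine_ivw(fit_m, fit_i, method: str = "elementwise") -> CorrectionResult:
    """Inverse-variance-weighted combination of two estimates of beta.

    The default weights each coefficient by the reciprocal of its own
    variance, beta_k = (b_Mk/v_Mk + b_Ik/v_Ik) / (1/v_Mk + 1/v_Ik), with
    combined variance (1/v_Mk + 1/v_Ik)^{-1}.  ``method="matrix"`` uses the
    full matrix-weighted form (V_M^{-1}+V_I^{-1})^{-1}(V_M^{-1}b_M +
    V_I^{-1}b_I) instead; the two coincide when the covariances are
    diagonal, and a material difference is logged.
    """
    b_m, v_m = _vcov_of(fit_m)
    b_i, v_i = _vcov_of(fit_i)
    if b_m.shape != b_i.shape:
        raise ValueError("coefficient vectors are not conformable")
    for name, v in (("M", v_m), ("I", v_i)):
        cond = np.linalg.cond(v)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"covariance of the {name} estimate is near-singular "
                f"(condition number {cond:.3g})")
    wm = np.linalg.inv(v_m)
    wi = np.linalg.inv(v_i)
    cov_mat = np.linalg.inv(wm + wi)
    beta_mat = cov_mat @ (wm @ b_m + wi @ b_i)
    dm, di = np.diag(v_m), np.diag(v_i)
    var_el = 1.0 / (1.0 / dm + 1.0 / di)
    beta_el = var_el * (b_m / dm + b_i / di)
    if method == "matrix":
        beta, cov = beta_mat, cov_mat
    elif method == "elementwise":
        beta, cov = beta_el, np.diag(var_el)
    else:
        raise ValueError(f"unknown IVW method {method!r}")
    gap = np.max(np.abs(beta_mat - beta_el) / np.sqrt(var_el))
    if gap > 0.5:
        log.info("matrix- and coefficient-wise IVW differ materially "
                 "(max %.2f combined-SE units)", gap)
    meta = fit_m if isinstance(fit_m, CorrectionResult) else fit_i
    return CorrectionResult(
        estimator="ivw",
        design=meta.design if isinstance(meta, CorrectionResult) else None,
        beta=beta, cov_beta=0.5 * (cov + cov.T),
        column_names=getattr(meta, "column_names", ()),
        rho=getattr(meta, "rho", 0.0), converged=True, n_iter=0,
        n_main=getattr(meta, "n_main", 0),
        n_validation=getattr(meta, "n_validation", 0))


def _diagnostic_value(beta, sigma2_eps, pieces) -> float:
    """Visit-averaged beta' Var(X|C,t,W) beta from independent residuals.

    Given the observed surrogate history, only the history column h (and
    h*t) of X is random; the cumulative average of independent calibration
    residuals has variance sigma2_eps * sum_k w_jk^2 (components drawn from
    observed true exposures contribute no residual variance).
    """
    total, count = 0.0, 0
    b1, b3 = beta[H_COL], beta[HT_COL]
    for piece in pieces:
        w2 = np.einsum("cjk,ck->cj", piece["Ws"] ** 2, piece["mask"])
        quad = (b1 + b3 * piece["times"]) ** 2 * sigma2_eps * w2
        total += float(quad.sum())
        count += quad.size
    return total / count


def approximation_diagnostic(result: CorrectionResult,
                             calib: CalibrationModel,
                             panel: Panel) -> float:
    """Estimate the Taylor-adequacy diagnostic beta' Var(X|C,t,W) beta.

    Propagates the calibration residual variance (assumed independent
    across visits) through the cumulative-average weights, forms the
    quadratic form in the fitted beta at every visit of ``panel``, and
    averages.  Values above 0.4 indicate the first-order approximation may
    be unreliable (a warning is logged).
    """
    df = panel.data
    times = df[TIME].to_numpy(dtype=float)
    pieces = []
    for _, idx in df.groupby(ID, sort=False).indices.items():
        t = times[idx]
        pieces.append({
            "Ws": batched_cumavg_weights(t[None, :]),
            "mask": np.ones((1, len(t))),
            "times": t[None, :],
        })
    value = _diagnostic_value(result.beta, calib.sigma2_eps, pieces)
    if value > 0.4:
        log.warning("approximation diagnostic %.3f exceeds 0.4", value)
    return value
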