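"""Synthetic-data generator and Monte Carlo study runner.

The generative design emulates a 5-wave longitudinal cohort with staggered
entry: entry times t_i1 ~ U(0,1) with unit spacing thereafter; surrogate
exposure C and an error-free covariate W drawn jointly multivariate normal
with AR(1) blocks (var 1, rho 0.6 for C; var 1, rho 0.2 for W) and
same-visit cross-covariance 0.4; the true exposure c from the linear
calibration model c = a0 + a1*C + a2*t + a3*C*t + a4*W + eps with
homoscedastic residual variance chosen to hit a target Cor(c, C) (or a
target value of the Taylor diagnostic); and correlated Bernoulli outcomes
from the marginal logit model on the true cumulative average with AR(1)
serial dependence (lag-1 correlation 0.1 on the binary scale, matched
through a Gaussian copula).

``run_study`` repeats generation + estimation over replicates and reports
percent relative bias (RBias), average reported SE (ASE), empirical SD of
estimates (ESE), and empirical 95% coverage (CP) per estimator and
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtri

from . import estimators as est
from .calibration import fit_calibration
from .gee import GeeError
from .panel import Panel

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "solve_residual_variance",
    "solve_diagnostic_variance",
    "resolve_config",
    "select_validation_visit",
    "generate_dataset",
    "run_study",
]

log = logging.getLogger(__name__)

_INNER_SEED = 20240915  # fixed stream for the variance solvers' MC samples


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the simulation design (see module docstring).

    ``sigma2_eps`` overrides the calibration residual variance directly;
    otherwise it is solved from ``target_diagnostic`` (if set) or
    ``target_cor``.  ``binary_corr_scale`` selects whether the outcome AR(1)
    parameter is matched on the binary scale (Gaussian-copula latent
    correlation calibrated numerically, the default) or imposed directly on
    the latent scale.
    """

    n1: int = 2000
    n2: int = 500
    n_reps: int = 500
    seed: int = 0
    n_visits: int = 5
    rho_c: float = 0.6
    rho_w: float = 0.2
    cross_cov: float = 0.4
    alpha: tuple = (1.2, 0.6, 0.5, 0.4, 0.3)
    beta: tuple = (-3.0, np.log(1.2), 0.5, -np.log(1.5), np.log(1.1))
    sigma2_eps: float | None = None
    target_cor: float = 0.90
    target_diagnostic: float | None = None
    outcome_rho: float = 0.1
    binary_corr_scale: str = "binary"
    validation: str = "single"
    design: str = "ms_evs"

    def __post_init__(self):
        if self.design not in ("ms_evs", "ms_ivs"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.validation not in ("single", "all"):
            raise ValueError(f"unknown validation completeness "
                             f"{self.validation!r}")
        if self.binary_corr_scale not in ("binary", "latent"):
            raise ValueError(f"unknown binary_corr_scale "
                             f"{self.binary_corr_scale!r}")


def _ar1_matrix(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def joint_cov(config: SimulationConfig) -> np.ndarray:
    """Assemble the 2m x 2m covariance of (C_1..C_m, W_1..W_m)."""
    m = config.n_visits
    V = np.zeros((2 * m, 2 * m))
    V[:m, :m] = _ar1_matrix(m, config.rho_c)
    V[m:, m:] = _ar1_matrix(m, config.rho_w)
    V[:m, m:] = config.cross_cov * np.eye(m)
    V[m:, :m] = config.cross_cov * np.eye(m)
    eigmin = np.linalg.eigvalsh(V).min()
    if eigmin <= 0:
        raise ValueError(f"exposure/covariate covariance not positive "
                         f"definite (min eigenvalue {eigmin:.3g})")
    return V


def _draw_design(config: SimulationConfig, n: int, rng):
    """Times, surrogate and covariate draws for n individuals."""
    m = config.n_visits
    t1 = rng.uniform(0.0, 1.0, size=n)
    times = t1[:, None] + np.arange(m)[None, :]
    L = np.linalg.cholesky(joint_cov(config))
    CW = rng.standard_normal((n, 2 * m)) @ L.T
    return times, CW[:, :m], CW[:, m:]


def _noiseless_true(config: SimulationConfig, times, C, W):
    a0, a1, a2, a3, a4 = config.alpha
    return a0 + a1 * C + a2 * times + a3 * C * times + a4 * W


def _cumavg_rows(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row-wise cumulative average with the first-visit convention."""
    n, m = values.shape
    s = np.empty_like(values)
    s[:, 0] = values[:, 0]
    gaps = np.diff(times, axis=1)
    for j in range(1, m):
        s[:, j] = (gaps[:, :j] * values[:, :j]).sum(axis=1) / (
            times[:, j] - times[:, 0])
    return s


# ---------------------------------------------------------------------------
# residual-variance solvers


def solve_residual_variance(config: SimulationConfig, target_cor: float,
                            n_mc: int = 100_000,
                            seed: int = _INNER_SEED) -> float:
    """Homoscedastic residual variance hitting a target Cor(c, C).

    The visit-averaged Pearson correlation between c and C is computed on a
    Monte Carlo sample of the noiseless design (fixed inner seed); because
    the residual is independent noise, the correlation at any sigma2 follows
    from the sample moments, and the one-dimensional root is bracketed and
    solved directly.  Correlation decreases in sigma2, so a target above the
    sigma2 = 0 value is unattainable.
    """
    if not 0.0 < target_cor < 1.0:
        raise ValueError("target correlation must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    times, C, W = _draw_design(config, n_mc, rng)
    c0 = _noiseless_true(config, times, C, W)
    m = config.n_visits
    cov = np.array([np.cov(c0[:, j], C[:, j])[0, 1] for j in range(m)])
    v0 = c0.var(axis=0, ddof=1)
    vC = C.var(axis=0, ddof=1)

    def avg_cor(sigma2):
        return float(np.mean(cov / np.sqrt((v0 + sigma2) * vC)))

    max_cor = avg_cor(0.0)
    if target_cor >= max_cor:
        raise ValueError(
            f"target correlation {target_cor} unattainable: maximum "
            f"achievable (sigma2=0) is {max_cor:.4f}")
    hi = 1.0
    while avg_cor(hi) > target_cor:
        hi *= 4.0
    return float(optimize.brentq(lambda s2: avg_cor(s2) - target_cor,
                                 0.0, hi, xtol=1e-10))


def solve_diagnostic_variance(config: SimulationConfig, target: float,
                              n_mc: int = 100_000,
                              seed: int = _INNER_SEED) -> float:
    """Residual variance making the visit-averaged Taylor diagnostic hit
    ``target``.

    The diagnostic beta' Var(X|C,t,W) beta equals
    sigma2 * mean_j[(beta1 + beta3 t_j)^2 * sum_k w_jk^2] for the cumulative
    average of independent residuals, so it is linear in sigma2 and the
    solution is target / K with K estimated over the entry-time law.
    """
    if target <= 0:
        raise ValueError("target diagnostic must be positive")
    rng = np.random.default_rng(seed)
    m = config.n_visits
    t1 = rng.uniform(0.0, 1.0, size=n_mc)
    times = t1[:, None] + np.arange(m)[None, :]
    # unit visit spacing: sum_k w_jk^2 = 1 at j=1 and 1/(j-1) for j >= 2
    sumw2 = np.concatenate([[1.0], 1.0 / np.arange(1, m)])
    b1, b3 = config.beta[1], config.beta[3]
    K = float(np.mean((b1 + b3 * times) ** 2 * sumw2[None, :]))
    if K <= 0:
        raise ValueError("diagnostic is identically zero for this beta: "
                         "any positive target is unattainable")
    return target / K


def _latent_rho(config: SimulationConfig, sigma2: float,
                n_sample: int = 2000, n_pairs: int = 400,
                seed: int = _INNER_SEED) -> float:
    """Gaussian-copula latent AR(1) parameter matching the target binary
    lag-1 correlation (or the target itself on the latent scale)."""
    target = config.outcome_rho
    if config.binary_corr_scale == "latent" or target == 0.0:
        return target
    rng = np.random.default_rng(seed)
    times, C, W = _draw_design(config, n_sample, rng)
    c = _noiseless_true(config, times, C, W) + rng.normal(
        scale=np.sqrt(sigma2), size=times.shape)
    s = _cumavg_rows(times, c)
    b0, b1, b2, b3, b4 = config.beta
    mu = expit(b0 + b1 * s + b2 * times + b3 * s * times + b4 * W)
    mu1 = mu[:, :-1].ravel()
    mu2 = mu[:, 1:].ravel()
    pick = rng.choice(len(mu1), size=min(n_pairs, len(mu1)), replace=False)
    mu1, mu2 = mu1[pick], mu2[pick]
    z1, z2 = ndtri(mu1), ndtri(mu2)
    sd = np.sqrt(mu1 * (1 - mu1) * mu2 * (1 - mu2))

    def achieved(r):
        dist = stats.multivariate_normal(mean=[0.0, 0.0],
                                         cov=[[1.0, r], [r, 1.0]],
                                         allow_singular=True)
        p11 = dist.cdf(np.column_stack([z1, z2]))
        return float(np.mean((p11 - mu1 * mu2) / sd))

    lo, hi = 1e-4, 0.95
    if achieved(hi) < target:
        raise ValueError(f"binary lag-1 correlation {target} unattainable")
    return float(optimize.brentq(lambda r: achieved(r) - target, lo, hi,
                                 xtol=1e-4))


@dataclass(frozen=True)
class ResolvedConfig:
    """A SimulationConfig with the derived generator constants filled in."""

    config: SimulationConfig
    sigma2_eps: float
    latent_rho: float


def resolve_config(config: SimulationConfig) -> ResolvedConfig:
    """Fill in sigma2_eps (from its target) and the copula latent rho."""
    if config.sigma2_eps is not None:
        sigma2 = config.sigma2_eps
    elif config.target_diagnostic is not None:
        sigma2 = solve_diagnostic_variance(config, config.target_diagnostic)
    else:
        sigma2 = solve_residual_variance(config, config.target_cor)
    return ResolvedConfig(config=config, sigma2_eps=sigma2,
                          latent_rho=_latent_rho(config, sigma2))


# ---------------------------------------------------------------------------
# data generation


def select_validation_visit(u) -> int:
    """Visit (1-based) at which the single true exposure is observed.

    Returns the rank of the first element of ``u`` among all five entries
    (ties broken by position: the first occurrence takes the lower rank);
    uniform on {1, ..., 5} in distribution.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or len(u) != 5:
        raise ValueError("u must be a vector of 5 uniforms")
    return int(1 + np.sum(u[1:] < u[0]))


def _selection_ranks(U: np.ndarray) -> np.ndarray:
    """Vectorized rank-of-first-element over rows (0-based visit index)."""
    return (U[:, 1:] < U[:, [0]]).sum(axis=1)


def generate_dataset(config: SimulationConfig, seed,
                     resolved: ResolvedConfig | None = None
                     ) -> tuple[Panel, Panel]:
    """Draw one (main, validation) panel pair; deterministic given seed.

    The outcome is generated from the marginal logit model on the *true*
    cumulative average, with AR(1) latent-normal serial dependence
    thresholded at ndtri(mu) so the marginals hold exactly.
    """
    if resolved is None:
        resolved = resolve_config(config)
    rng = np.random.default_rng(seed)
    m = config.n_visits
    n = config.n1 + config.n2
    times, C, W = _draw_design(config, n, rng)
    c = _noiseless_true(config, times, C, W) + rng.normal(
        scale=np.sqrt(resolved.sigma2_eps), size=(n, m))
    s = _cumavg_rows(times, c)
    b0, b1, b2, b3, b4 = config.beta
    mu = expit(b0 + b1 * s + b2 * times + b3 * s * times + b4 * W)
    e = rng.standard_normal((n, m))
    z = np.empty_like(e)
    lr = resolved.latent_rho
    z[:, 0] = e[:, 0]
    for j in range(1, m):
        z[:, j] = lr * z[:, j - 1] + np.sqrt(1.0 - lr * lr) * e[:, j]
    y = (z < ndtri(mu)).astype(float)

    n1, n2 = config.n1, config.n2
    ids = np.repeat(np.arange(1, n + 1), m)
    flat = dict(id=ids, time=times.ravel(), C=C.ravel(), W=W.ravel())
    df = pd.DataFrame(flat)
    df["y"] = y.ravel()
    df["c"] = np.nan

    is_val = np.repeat(np.arange(n) >= n1, m)
    c_col = np.full(n * m, np.nan)
    if config.validation == "all":
        c_col[is_val] = c[n1:].ravel()
    else:
        U = rng.uniform(size=(n2, m))
        sel = _selection_ranks(U)
        val_c = np.full((n2, m), np.nan)
        val_c[np.arange(n2), sel] = c[n1:][np.arange(n2), sel]
        c_col[is_val] = val_c.ravel()
    df["c"] = c_col
    df["role"] = np.where(is_val,
                          "IVS" if config.design == "ms_ivs" else "EVS",
                          "MS")
    if config.design == "ms_evs":
        df.loc[is_val, "y"] = np.nan
    main = Panel(df[~is_val].reset_index(drop=True), covariates=("W",))
    validation = Panel(df[is_val].reset_index(drop=True), covariates=("W",))
    return main, validation


# ---------------------------------------------------------------------------
# study runner


@dataclass
class SimulationSummary:
    """RBias/ASE/ESE/CP table plus per-replicate estimates."""

    table: pd.DataFrame
    n_reps: int
    n_converged: dict
    sigma2_eps: float
    latent_rho: float
    config: SimulationConfig
    estimates: dict = field(repr=False, default_factory=dict)
    ses: dict = field(repr=False, default_factory=dict)

    def row(self, estimator: str, coef: str = "h_x_t") -> pd.Series:
        return self.table.loc[(estimator, coef)]


def _default_estimators(design: str) -> tuple[str, ...]:
    if design == "ms_ivs":
        return ("naive", "corrected", "corrected_true", "ivs_only", "ivw")
    return ("naive", "corrected")


def _one_replicate(config, resolved, seed, which, outcome_corr):
    main, validation = generate_dataset(config, seed, resolved)
    out = {}

    def record(name, beta, cov):
        out[name] = (np.asarray(beta), np.sqrt(np.diag(cov)))

    try:
        calib = fit_calibration(validation, corr="ar1")
    except GeeError as exc:
        log.warning("calibration failed: %s", exc)
        return {name: None for name in which}

    if config.design == "ms_ivs":
        analysis_panel = Panel(
            pd.concat([main.data, validation.data], ignore_index=True),
            covariates=main.covariates)
    else:
        analysis_panel = main

    for name in which:
        try:
            if name == "naive":
                r = est.fit_naive(analysis_panel, corr=outcome_corr)
                record(name, r.beta, r.cov_beta)
            elif name == "corrected":
                r = est.fit_corrected(
                    main, calib, corr=outcome_corr, design=config.design,
                    validation=validation if config.design == "ms_ivs"
                    else None)
                record(name, r.beta, r.cov_beta)
            elif name == "corrected_true":
                r = est.fit_corrected_true_ivs(main, validation, calib,
                                               corr=outcome_corr)
                record(name, r.beta, r.cov_beta)
            elif name in ("ivs_only", "ivw"):
                if "_ivs_fit" not in out:
                    out["_ivs_fit"] = est.fit_ivs_only(validation)
                fit_i = out["_ivs_fit"]
                if name == "ivs_only":
                    b, v = est._vcov_of(fit_i)
                    record(name, b, v)
                else:
                    if "_corrected_ms" not in out:
                        out["_corrected_ms"] = est.fit_corrected(
                            main, calib, corr=outcome_corr, design="ms_evs")
                    r = est.combine_ivw(out["_corrected_ms"], fit_i)
                    record(name, r.beta, r.cov_beta)
            else:
                raise ValueError(f"unknown estimator {name!r}")
        except (GeeError, np.linalg.LinAlgError) as exc:
            log.warning("replicate estimator %s failed: %s", name, exc)
            out[name] = None
    return {name: out.get(name) for name in which}


def run_study(config: SimulationConfig, which: tuple[str, ...] | None = None,
              outcome_corr: str = "ar1", n_jobs: int = 1) -> SimulationSummary:
    """Run the full Monte Carlo study and summarize operating characteristics.

    Replicate seeds are spawned from ``config.seed`` via a counter-based
    seed sequence, so results are identical regardless of parallel
    scheduling (``n_jobs``).
    """
    which = which or _default_estimators(config.design)
    resolved = resolve_config(config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(config, resolved, s, which, outcome_corr)
            for s in children)
    else:
        results = [_one_replicate(config, resolved, s, which, outcome_corr)
                   for s in children]

    beta_true = np.asarray(config.beta, dtype=float)
    coef_names = ["const", "h", "t", "h_x_t", "W"][:len(beta_true)]
    rows = []
    estimates, ses, n_converged = {}, {}, {}
    for name in which:
        oks = [r[name] for r in results if r[name] is not None]
        n_converged[name] = len(oks)
        if not oks:
            continue
        B = np.vstack([b for b, _ in oks])
        S = np.vstack([s for _, s in oks])
        estimates[name], ses[name] = B, S
        mean = B.mean(axis=0)
        bias = mean - beta_true
        with np.errstate(divide="ignore", invalid="ignore"):
            rbias = np.where(beta_true != 0, 100.0 * bias / beta_true, np.nan)
        ase = S.mean(axis=0)
        ese = B.std(axis=0, ddof=1)
        cover = (np.abs(B - beta_true) <= est.Z95 * S).mean(axis=0)
        for k, coef in enumerate(coef_names):
            rows.append({
                "estimator": name, "coef": coef, "true": beta_true[k],
                "mean": mean[k], "bias": bias[k], "rbias_pct": rbias[k],
                "ase": ase[k], "ese": ese[k], "cp": cover[k],
                "n_converged": len(oks),
            })
    table = pd.DataFrame(rows).set_index(["estimator", "coef"])
    return SimulationSummary(
        table=table, n_reps=config.n_reps, n_converged=n_converged,
        sigma2_eps=resolved.sigma2_eps, latent_rho=resolved.latent_rho,
        config=config, estimates=estimates, ses=ses)
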