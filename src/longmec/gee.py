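"""Minimal GEE solver exposing per-cluster score and bread pieces.

Fits marginal mean models g(mu) = X'beta by Fisher scoring of the estimating
equation sum_i D_i' V_i^{-1} (y_i - mu_i) = 0, with logit / identity / log
links and independence / exchangeable / AR(1) working correlation.  The
correlation parameter rho is re-estimated by moments after each coefficient
step.  Clusters are processed in batches of equal size with stacked linear
algebra, which keeps 5000-cluster fits in the tens of milliseconds.

The per-cluster scores psi_i = D_i' V_i^{-1} (y_i - mu_i) and the bread
H = sum_i D_i' V_i^{-1} D_i are retained on the fit object: they are the
building blocks of the stacked measurement-error sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinkSpec",
    "WorkingCorrelation",
    "GeeFit",
    "fit_gee",
    "estimate_rho",
    "GeeError",
    "GeeConvergenceError",
    "GeeDivergenceError",
    "UndefinedRhoError",
]

_ETA_MAX = 30.0  # |linear predictor| beyond this flags separation-like divergence


class GeeError(RuntimeError):
    pass


class GeeConvergenceError(GeeError):
    """Fisher scoring failed to converge; carries the last iterate."""

    def __init__(self, msg: str, last_fit: "GeeFit | None" = None):
        super().__init__(msg)
        self.last_fit = last_fit


class GeeDivergenceError(GeeError):
    pass


class UndefinedRhoError(GeeError):
    pass


# ---------------------------------------------------------------------------
# links and working correlation


@dataclass(frozen=True)
class LinkSpec:
    """Link function g with mean g^{-1}, its derivatives, and variance fn."""

    name: str

    def inverse(self, eta: np.ndarray) -> np.ndarray:
        if self.name == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        if self.name == "identity":
            return eta
        if self.name == "log":
            return np.exp(eta)
        raise ValueError(f"unknown link {self.name!r}")

    def dinv(self, eta: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """d g^{-1} / d eta, evaluated via mu for stability."""
        if self.name == "logit":
            return mu * (1.0 - mu)
        if self.name == "identity":
            return np.ones_like(eta)
        return mu  # log

    def d2inv(self, eta: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Second derivative of g^{-1}; used by the Taylor diagnostic and
        the analytic cross block of the stacked sandwich."""
        if self.name == "logit":
            return mu * (1.0 - mu) * (1.0 - 2.0 * mu)
        if self.name == "identity":
            return np.zeros_like(eta)
        return mu  # log

    def variance(self, mu: np.ndarray) -> np.ndarray:
        """Variance function (unit dispersion)."""
        if self.name == "logit":
            return mu * (1.0 - mu)
        if self.name == "identity":
            return np.ones_like(mu)
        return mu  # log

    @property
    def has_dispersion(self) -> bool:
        # binary variance mu(1-mu) carries no scale; identity/log estimate one
        return self.name != "logit"


def get_link(link) -> LinkSpec:
    if isinstance(link, LinkSpec):
        return link
    if link not in ("logit", "identity", "log"):
        raise ValueError(f"unknown link {link!r}")
    return LinkSpec(link)


@dataclass(frozen=True)
class WorkingCorrelation:
    """Working correlation structure; ``rho=None`` means moment-estimated.

    AR(1) correlation is indexed by visit order (rho^|j-k|); set
    ``by_time_gap=True`` for rho^|t_j-t_k| instead.
    """

    structure: str = "independence"
    rho: float | None = None
    by_time_gap: bool = False

    def __post_init__(self):
        if self.structure not in ("independence", "exchangeable", "ar1"):
            raise ValueError(f"unknown working correlation {self.structure!r}")
        if self.rho is not None and not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")

    def matrix(self, m: int, rho: float,
               times: np.ndarray | None = None) -> np.ndarray:
        if self.structure == "independence" or m == 1:
            return np.eye(m)
        if self.structure == "exchangeable":
            return np.full((m, m), rho) + (1.0 - rho) * np.eye(m)
        if self.by_time_gap and times is not None:
            lag = np.abs(times[:, None] - times[None, :])
        else:
            idx = np.arange(m)
            lag = np.abs(idx[:, None] - idx[None, :])
        return np.sign(rho) ** lag * np.abs(rho) ** lag if rho < 0 else rho ** lag


def get_corr(corr) -> WorkingCorrelation:
    if isinstance(corr, WorkingCorrelation):
        return corr
    return WorkingCorrelation(corr)


# ---------------------------------------------------------------------------
# cluster batching


@dataclass
class _Batch:
    """All clusters of one common size, stacked."""

    idx: np.ndarray      # (ncl, m) row indices into the pooled data
    X: np.ndarray        # (ncl, m, p)
    y: np.ndarray        # (ncl, m)
    times: np.ndarray | None  # (ncl, m) visit times (gap-based AR(1) only)
    cluster_pos: np.ndarray   # (ncl,) position of each cluster in global order


def _make_batches(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                  times: np.ndarray | None) -> tuple[list[_Batch], int]:
    """Group rows by cluster, then batch clusters of equal size."""
    groups = np.asarray(groups)
    # stable order of first appearance
    _, start_idx, inv = np.unique(groups, return_index=True, return_inverse=True)
    order = np.argsort(start_idx, kind="mergesort")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    cluster_of_row = rank[inv]          # 0..ncl-1 in order of first appearance
    ncl = len(order)
    sizes = np.bincount(cluster_of_row)
    row_order = np.argsort(cluster_of_row, kind="mergesort")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    batches = []
    for m in np.unique(sizes):
        cl = np.flatnonzero(sizes == m)
        idx = np.stack([row_order[offsets[c]:offsets[c] + m] for c in cl])
        batches.append(_Batch(
            idx=idx, X=X[idx], y=y[idx],
            times=None if times is None else times[idx],
            cluster_pos=cl,
        ))
    return batches, ncl


# ---------------------------------------------------------------------------
# rho estimation


def estimate_rho(residuals: list[np.ndarray], structure: str) -> float:
    """Moment estimate of the working-correlation parameter.

    ``residuals`` are per-cluster standardized residual vectors.  The
    exchangeable estimate averages within-cluster cross-products over all
    pairs; the AR(1) estimate averages lag-1 products over adjacent visits.
    Both are normalized by the overall mean square and clipped to
    (-0.99, 0.99).
    """
    if structure == "independence":
        return 0.0
    if structure not in ("exchangeable", "ar1"):
        raise ValueError(f"unknown structure {structure!r}")
    if all(len(e) < 2 for e in residuals):
        raise UndefinedRhoError(
            f"all clusters singleton: rho undefined for {structure!r}")
    num = 0.0
    npairs = 0
    ss = 0.0
    nobs = 0
    for e in residuals:
        e = np.asarray(e, dtype=float)
        ss += float(e @ e)
        nobs += len(e)
        if len(e) < 2:
            continue
        if structure == "ar1":
            num += float(e[:-1] @ e[1:])
            npairs += len(e) - 1
        else:
            s = e.sum()
            num += 0.5 * (s * s - float(e @ e))
            npairs += len(e) * (len(e) - 1) // 2
    phi = ss / nobs
    if phi <= 0 or npairs == 0:
        raise UndefinedRhoError("degenerate residuals: rho undefined")
    return float(np.clip(num / (npairs * phi), -0.99, 0.99))


def _rho_phi_from_batches(batches, mu, var, y, p, structure):
    """Vectorized moment estimates of (rho, phi) from Pearson residuals."""
    nobs = len(y)
    e = (y - mu) / np.sqrt(var)
    phi = float(e @ e) / max(nobs - p, 1)
    if structure == "independence":
        return 0.0, phi
    num = 0.0
    npairs = 0
    for b in batches:
        eb = e[b.idx]  # (ncl, m)
        m = eb.shape[1]
        if m < 2:
            continue
        if structure == "ar1":
            num += float(np.sum(eb[:, :-1] * eb[:, 1:]))
            npairs += eb.shape[0] * (m - 1)
        else:
            s = eb.sum(axis=1)
            num += 0.5 * float(np.sum(s * s) - np.sum(eb * eb))
            npairs += eb.shape[0] * m * (m - 1) // 2
    if npairs == 0:
        raise UndefinedRhoError(
            f"all clusters singleton: rho undefined for {structure!r}")
    denom = max(npairs - p, 1) * phi
    return float(np.clip(num / denom, -0.99, 0.99)), phi


# ---------------------------------------------------------------------------
# the fit object


@dataclass
class GeeFit:
    """A converged (or best-effort) GEE solution with sandwich ingredients."""

    beta: np.ndarray
    link: LinkSpec
    corr: WorkingCorrelation
    rho: float
    dispersion: float
    cov_naive: np.ndarray
    cov_robust: np.ndarray
    bread: np.ndarray             # H = sum_i D_i' V_i^{-1} D_i
    cluster_scores: np.ndarray    # (ncl, p) psi_i at the solution
    n_clusters: int
    n_obs: int
    n_iter: int
    converged: bool
    column_names: tuple[str, ...] = ()
    _batches: list = field(default_factory=list, repr=False)
    _vinv: list = field(default_factory=list, repr=False)   # per batch (ncl,m,m)
    _mu: list = field(default_factory=list, repr=False)     # per batch (ncl,m)

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def score(self) -> np.ndarray:
        """Total estimating function at the solution (zero to tolerance)."""
        return self.cluster_scores.sum(axis=0)


def _batch_quantities(b: _Batch, beta, link: LinkSpec, corr: WorkingCorrelation,
                      rho: float):
    """Per-batch mu, dmu, Vinv and solve pieces at the current beta."""
    eta = b.X @ beta                       # (ncl, m)
    if link.name != "identity" and np.max(np.abs(eta)) > _ETA_MAX:
        raise GeeDivergenceError(
            f"linear predictor out of range (|eta|max="
            f"{float(np.max(np.abs(eta))):.1f}): separation-like divergence")
    mu = link.inverse(eta)
    dmu = link.dinv(eta, mu)
    a = link.variance(mu)
    m = b.X.shape[1]
    if corr.by_time_gap and b.times is not None and m > 1:
        # gap-based AR(1): R varies per cluster
        lag = np.abs(b.times[:, :, None] - b.times[:, None, :])
        R = rho ** lag if rho >= 0 else np.sign(rho) ** lag * np.abs(rho) ** lag
    else:
        R = corr.matrix(m, rho, None)[None, :, :]
    sa = np.sqrt(a)
    V = sa[:, :, None] * R * sa[:, None, :]
    return eta, mu, dmu, V


def fit_gee(X, y, groups, link="logit", corr="independence", *,
            times=None, tol=1e-8, maxiter=100,
            column_names=()) -> GeeFit:
    """Fit a marginal mean model by GEE Fisher scoring.

    Parameters
    ----------
    X, y:
        Pooled design matrix (n, p) and response (n,).
    groups:
        Cluster labels per row; rows of one cluster must be in visit order.
    link, corr:
        Link name or :class:`LinkSpec`; structure name or
        :class:`WorkingCorrelation`.
    times:
        Visit times per row; only consulted for gap-based AR(1).

    Initialization is the independence GLM fit (one scoring pass with
    R = I); each iteration alternates a beta step and a rho moment step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    link = get_link(link)
    corr = get_corr(corr)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise GeeError("design matrix is rank deficient")
    times_arr = None if times is None else np.asarray(times, dtype=float)
    batches, ncl = _make_batches(X, y, groups, times_arr)
    if corr.structure != "independence" and all(
            b.X.shape[1] < 2 for b in batches):
        raise UndefinedRhoError(
            f"all clusters singleton: rho undefined for {corr.structure!r}")

    # init: independence GLM (identity start at OLS, others at zero)
    if link.name == "identity":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        beta = np.zeros(p)
        # a few IRLS passes under independence for a stable start
        for _ in range(10):
            eta = X @ beta
            mu = link.inverse(eta)
            dmu = link.dinv(eta, mu)
            a = np.maximum(link.variance(mu), 1e-10)
            w = dmu * dmu / a
            z = (y - mu) / np.maximum(dmu, 1e-10)
            WX = X * w[:, None]
            step = np.linalg.solve(X.T @ WX, WX.T @ z)
            beta = beta + step
            if np.max(np.abs(step) / (1.0 + np.abs(beta))) < 1e-10:
                break

    rho = corr.rho if corr.rho is not None else 0.0
    fixed_rho = corr.rho is not None
    dispersion = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        # rho/phi moment step from current residuals
        eta = X @ beta
        mu = link.inverse(eta)
        var = np.maximum(link.variance(mu), 1e-12)
        if fixed_rho:
            _, dispersion = _rho_phi_from_batches(
                batches, mu, var, y, p, "independence")
        else:
            rho, dispersion = _rho_phi_from_batches(
                batches, mu, var, y, p, corr.structure)
        # beta step
        H = np.zeros((p, p))
        score = np.zeros(p)
        for b in batches:
            _, mub, dmub, V = _batch_quantities(b, beta, link, corr, rho)
            D = dmub[:, :, None] * b.X                  # (ncl, m, p)
            rhs = np.concatenate([D, (b.y - mub)[:, :, None]], axis=2)
            sol = np.linalg.solve(V, rhs)               # V^{-1} [D r]
            ViD, Vir = sol[:, :, :p], sol[:, :, p]
            H += np.einsum("cmp,cmq->pq", D, ViD)
            score += np.einsum("cmp,cm->p", D, Vir)
        delta = np.linalg.solve(H, score)
        beta = beta + delta
        if np.max(np.abs(delta) / (1.0 + np.abs(beta))) < tol:
            converged = True
            break

    # final pieces at the solution
    H = np.zeros((p, p))
    scores = np.zeros((ncl, p))
    vinv_store, mu_store = [], []
    for b in batches:
        _, mub, dmub, V = _batch_quantities(b, beta, link, corr, rho)
        D = dmub[:, :, None] * b.X
        Vinv = np.linalg.inv(V)
        ViD = Vinv @ D
        H += np.einsum("cmp,cmq->pq", D, ViD)
        scores[b.cluster_pos] = np.einsum("cmp,cm->cp", ViD, b.y - mub)
        vinv_store.append(Vinv)
        mu_store.append(mub)
    Hinv = np.linalg.inv(H)
    meat = scores.T @ scores
    cov_robust = Hinv @ meat @ Hinv.T
    cov_naive = (dispersion if link.has_dispersion else 1.0) * Hinv
    fit = GeeFit(
        beta=beta, link=link, corr=corr, rho=rho,
        dispersion=dispersion if link.has_dispersion else 1.0,
        cov_naive=cov_naive, cov_robust=cov_robust, bread=H,
        cluster_scores=scores, n_clusters=ncl, n_obs=n,
        n_iter=n_iter, converged=converged,
        column_names=tuple(column_names),
        _batches=batches, _vinv=vinv_store, _mu=mu_store,
    )
    if not converged:
        raise GeeConvergenceError(
            f"GEE did not converge in {maxiter} iterations", last_fit=fit)
    return fit
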