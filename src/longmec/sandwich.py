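"""Stacked M-estimation variance for the two-step corrected estimator.

The calibration step solves psi_alpha = 0 in the validation study and the
outcome step solves psi_beta = 0 in the main analysis set with alpha_hat
plugged in.  Treating theta = (alpha', beta')' as the solution of the joint
estimating equation psi = (psi_alpha', psi_beta')' = 0 gives the sandwich

    Var(theta_hat) = B^{-1} A B^{-1}',   B = E d psi / d theta,  A = Var(psi),

estimated by the empirical bread and outer-product meat over individuals.
The alpha-equation never involves beta, so B is block lower-triangular; the
cross block d psi_beta / d alpha flows through the chain
c_hat -> s_hat -> X_hat -> mu and is computed analytically (a
central-difference version is provided as a verification oracle).

Under MS/EVS the two samples are independent, so no individual contributes
to both components and the meat is block-diagonal; under MS/IVS the IVS
individuals contribute both scores jointly and the cross-products are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationModel
from .gee import GeeFit

__all__ = [
    "CrossPieces",
    "cross_block_analytic",
    "cross_block_numeric",
    "stacked_sandwich",
    "bootstrap_variance",
    "SingularBreadError",
]

#: fixed layout of the outcome design (1, h, t, h*t, W...)
H_COL, HT_COL = 1, 3


class SingularBreadError(np.linalg.LinAlgError):
    pass


@dataclass
class CrossPieces:
    """Chain-rule ingredients aligned with the outcome fit's cluster batches.

    One entry per batch, each a dict with keys:

    - ``Z``: (ncl, m, p_alpha) calibration design rows at the outcome visits;
    - ``Ws``: (ncl, m, m) history weight matrices (s = Ws @ point exposure);
    - ``mask``: (ncl, m) 1.0 where the exposure series uses c_hat(alpha),
      0.0 where an observed true exposure was substituted;
    - ``fixed``: (ncl, m) the alpha-free part of the series (observed c);
    - ``times``: (ncl, m) visit times.
    """

    batches: list[dict]
    p_alpha: int


def _dseries(piece: dict) -> np.ndarray:
    """d s_hat / d alpha per batch: Ws @ (mask * Z), shape (ncl, m, p_a)."""
    return np.einsum("cjk,ckp->cjp", piece["Ws"],
                     piece["mask"][:, :, None] * piece["Z"])


def cross_block_analytic(fit: GeeFit, cross: CrossPieces,
                         beta: np.ndarray) -> np.ndarray:
    """Analytic d psi_beta / d alpha with the working covariance held fixed.

    psi_beta = sum_i X_i' Delta_i V_i^{-1} (y_i - mu_i); alpha enters through
    the history column h (and h*t) of X_i and through mu_i.  Differentiating
    with V_i fixed at the fitted value yields three terms: the design term
    (dX'/da) Delta u, the curvature term X' diag(mu'' deta/da) u, and the
    mean term -X' Delta V^{-1} Delta (deta/da), where u = V^{-1}(y - mu).
    """
    pb = len(beta)
    out = np.zeros((pb, cross.p_alpha))
    b1, b3 = beta[H_COL], beta[HT_COL]
    for b, Vinv, mu, piece in zip(fit._batches, fit._vinv, fit._mu,
                                  cross.batches):
        X, y, t = b.X, b.y, piece["times"]
        eta = X @ beta
        dmu = fit.link.dinv(eta, mu)
        d2mu = fit.link.d2inv(eta, mu)
        r = y - mu
        u = np.einsum("cjk,ck->cj", Vinv, r)
        dS = _dseries(piece)                         # (ncl, m, pa)
        G = (b1 + b3 * t)[:, :, None] * dS           # deta/dalpha
        du = dmu * u
        # design term: rows h and h*t of dX'/dalpha pick up dS and t*dS
        out[H_COL] += np.einsum("cj,cjp->p", du, dS)
        out[HT_COL] += np.einsum("cj,cjp->p", du * t, dS)
        # curvature term
        out += np.einsum("cjq,cj,cjp->qp", X, d2mu * u, G)
        # mean term
        D = dmu[:, :, None] * X
        out -= np.einsum("cjq,cjk,ckp->qp", D, Vinv,
                         dmu[:, :, None] * G)
    return out


def _psi_beta_at_alpha(fit: GeeFit, cross: CrossPieces, beta: np.ndarray,
                       alpha: np.ndarray) -> np.ndarray:
    """Total outcome score as a function of alpha, V fixed at the fit."""
    pb = len(beta)
    total = np.zeros(pb)
    for b, Vinv, piece in zip(fit._batches, fit._vinv, cross.batches):
        chat = piece["Z"] @ alpha
        series = piece["mask"] * chat + piece["fixed"]
        h = np.einsum("cjk,ck->cj", piece["Ws"], series)
        X = b.X.copy()
        X[:, :, H_COL] = h
        X[:, :, HT_COL] = h * piece["times"]
        eta = X @ beta
        mu = fit.link.inverse(eta)
        dmu = fit.link.dinv(eta, mu)
        D = dmu[:, :, None] * X
        u = np.einsum("cjk,ck->cj", Vinv, b.y - mu)
        total += np.einsum("cjp,cj->p", D, u)
    return total


def cross_block_numeric(fit: GeeFit, cross: CrossPieces, beta: np.ndarray,
                        alpha: np.ndarray) -> np.ndarray:
    """Central-difference d psi_beta / d alpha (verification oracle)."""
    pa = len(alpha)
    out = np.zeros((len(beta), pa))
    for k in range(pa):
        step = 1e-6 * (1.0 + abs(alpha[k]))
        hi, lo = alpha.copy(), alpha.copy()
        hi[k] += step
        lo[k] -= step
        out[:, k] = (_psi_beta_at_alpha(fit, cross, beta, hi)
                     - _psi_beta_at_alpha(fit, cross, beta, lo)) / (2 * step)
    return out


def stacked_sandwich(calib: CalibrationModel, outcome: GeeFit,
                     outcome_ids: np.ndarray, Bba: np.ndarray,
                     design: str, small_sample: bool = False) -> np.ndarray:
    """Covariance of theta_hat = (alpha_hat', beta_hat')'.

    Parameters
    ----------
    calib, outcome:
        Fitted calibration model and outcome GEE (scores and breads retained).
    outcome_ids:
        Individual id per outcome cluster, in the fit's cluster order; matched
        against ``calib.cluster_ids`` to decide which individuals contribute
        both score components (MS/IVS) or only one (MS/EVS).
    Bba:
        Cross block d psi_beta / d alpha.
    small_sample:
        Apply an optional N/(N - p) inflation to the meat.
    """
    pa, pb = len(calib.alpha), len(outcome.beta)
    B = np.zeros((pa + pb, pa + pb))
    B[:pa, :pa] = -calib.bread
    B[pa:, pa:] = -outcome.bread
    B[pa:, :pa] = Bba

    calib_pos = {cid: i for i, cid in enumerate(calib.cluster_ids)}
    out_pos = {cid: i for i, cid in enumerate(outcome_ids)}
    all_ids = list(dict.fromkeys(list(out_pos) + list(calib_pos)))
    psi = np.zeros((len(all_ids), pa + pb))
    for row, cid in enumerate(all_ids):
        if cid in calib_pos:
            psi[row, :pa] = calib.cluster_scores[calib_pos[cid]]
        if cid in out_pos:
            psi[row, pa:] = outcome.cluster_scores[out_pos[cid]]
    if design == "ms_evs" and set(calib_pos) & set(out_pos):
        raise ValueError("MS/EVS design but validation ids appear in the "
                         "outcome analysis set")
    A = psi.T @ psi
    if small_sample:
        n = len(all_ids)
        A *= n / max(n - (pa + pb), 1)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        blk = "alpha" if np.linalg.matrix_rank(calib.bread) < pa else "beta"
        raise SingularBreadError(
            f"singular bread matrix ({blk} block)") from None
    cov = Binv @ A @ Binv.T
    return 0.5 * (cov + cov.T)


def bootstrap_variance(panels: dict, estimator, n_boot: int = 200,
                       seed: int = 0) -> np.ndarray:
    """Nonparametric cluster bootstrap of the full two-step estimator.

    ``panels`` maps stratum name -> Panel; individuals are resampled with
    replacement within each stratum, relabelled to stay distinct clusters,
    and ``estimator(panels_resampled)`` must return a coefficient vector.
    Returns the empirical covariance over converged resamples.  Resamples
    that fail to converge are dropped with a warning; more than 20% dropped
    is an oracle failure.
    """
    import logging

    from .panel import ID, Panel

    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    rng = np.random.default_rng(seed)
    log = logging.getLogger(__name__)
    draws = []
    failed = 0
    for _ in range(n_boot):
        resampled = {}
        for name, panel in panels.items():
            df = panel.data
            idx_map = df.groupby(ID, sort=False).indices
            blocks = list(idx_map.values())
            chosen = rng.choice(len(blocks), size=len(blocks), replace=True)
            rows = np.concatenate([blocks[j] for j in chosen])
            sizes = np.array([len(blocks[j]) for j in chosen])
            new = df.iloc[rows].reset_index(drop=True)
            # relabel so each draw stays a distinct cluster (stratum-prefixed
            # to keep ids unique across panels)
            labels = np.array([f"{name}_{i}" for i in range(len(chosen))])
            new[ID] = np.repeat(labels, sizes)
            resampled[name] = Panel(new, covariates=panel.covariates)
        try:
            draws.append(np.asarray(estimator(resampled)))
        except Exception as exc:  # non-convergent resample
            failed += 1
            log.warning("bootstrap resample dropped: %s", exc)
    if failed > 0.2 * n_boot:
        raise RuntimeError(
            f"bootstrap oracle failure: {failed}/{n_boot} resamples dropped")
    draws = np.vstack(draws)
    return np.cov(draws, rowvar=False, ddof=1)
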