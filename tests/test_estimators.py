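"""Outcome estimators: equivalences, IVW closed forms, diagnostic."""

import copy

import numpy as np
import pytest

from longmec import estimators as est
from longmec import simulate as sim
from longmec.calibration import fit_calibration
from longmec.panel import Panel

from conftest import make_panel


@pytest.fixture(scope="module")
def fitted(small_dataset):
    main, val = small_dataset
    calib = fit_calibration(val, corr="ar1")
    return main, val, calib


def test_identity_calibration_equivalence(fitted):
    """With c_hat = C the corrected fit equals the naive fit exactly."""
    main, _, calib = fitted
    ident = copy.copy(calib)
    ident.alpha = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    corrected = est.fit_corrected(main, ident)
    naive = est.fit_naive(main)
    np.testing.assert_array_equal(corrected.beta, naive.beta)


def test_corrected_uses_stacked_variance(fitted):
    """Stacked SEs differ from (and the alpha block exists alongside) the
    plain robust GEE SEs."""
    main, _, calib = fitted
    res = est.fit_corrected(main, calib)
    assert res.cov_theta.shape == (10, 10)
    # covariance symmetric PSD
    np.testing.assert_allclose(res.cov_theta, res.cov_theta.T, atol=1e-12)
    assert np.linalg.eigvalsh(res.cov_theta).min() > -1e-10
    assert not np.allclose(res.se, res.fit.se_robust)


def test_corrected_true_ivs_reduces_without_observed_c(ivs_dataset):
    """No observed c anywhere in the IVS: the true-exposure variant equals
    the plain corrected fit."""
    main, val = ivs_dataset
    calib = fit_calibration(val, corr="ar1")
    blank = Panel(val.data.assign(c=np.nan), covariates=val.covariates)
    a = est.fit_corrected(main, calib, design="ms_ivs", validation=blank)
    b = est.fit_corrected_true_ivs(main, blank, calib)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_allclose(a.cov_beta, b.cov_beta, atol=1e-12)


def test_corrected_true_requires_ivs(fitted):
    main, val, calib = fitted
    with pytest.raises(ValueError, match="MS/IVS"):
        est.fit_corrected_true_ivs(main, val, calib, design="ms_evs")


def test_ivs_only_single_visit_design_rows():
    """Single-measurement rule builds (1, c, t, c*t, W) at selected visits."""
    rng = np.random.default_rng(4)
    rows, expected = [], []
    for i in range(40):
        cvisit = int(rng.integers(0, 5))
        cval = float(rng.normal())
        w = float(rng.normal())
        for j in range(5):
            rows.append((i, float(j), float(rng.integers(0, 2)),
                         0.1 * j, cval if j == cvisit else np.nan, w, "IVS"))
        expected.append([1.0, cval, float(cvisit), cval * cvisit, w])
    panel = make_panel(rows)
    fit = est.fit_ivs_only(panel)
    assert fit.n_obs == 40 and fit.n_clusters == 40
    assert tuple(fit.column_names) == ("const", "h", "t", "h_x_t", "W")
    built = np.vstack([b.X.reshape(-1, 5) for b in fit._batches])
    np.testing.assert_allclose(np.sort(built, axis=0),
                               np.sort(np.array(expected), axis=0),
                               atol=1e-12)


def test_ivs_only_complete_equals_naive_on_true(ivs_dataset):
    """Fully observed c identical to C makes IVS-only equal the naive fit."""
    _, val = ivs_dataset
    df = val.data.copy()
    df["c"] = df["C"]
    panel = Panel(df, covariates=val.covariates)
    fit = est.fit_ivs_only(panel)
    naive = est.fit_naive(panel)
    np.testing.assert_allclose(fit.beta, naive.beta, atol=1e-10)


class TestCombineIVW:
    def _mk(self, beta, cov):
        return est.CorrectionResult(
            estimator="corrected", design="ms_ivs",
            beta=np.asarray(beta, float), cov_beta=np.asarray(cov, float),
            column_names=("a", "b")[:len(beta)], rho=0.0, converged=True,
            n_iter=1, n_main=10)

    def test_equal_variances_average(self):
        a = self._mk([1.0, 3.0], np.eye(2))
        b = self._mk([3.0, 1.0], np.eye(2))
        res = est.combine_ivw(a, b)
        np.testing.assert_allclose(res.beta, [2.0, 2.0])

    def test_scalar_closed_form(self):
        a = self._mk([1.0], [[1.0]])
        b = self._mk([3.0], [[3.0]])
        res = est.combine_ivw(a, b)
        assert res.beta[0] == pytest.approx(1.5)
        assert res.cov_beta[0, 0] == pytest.approx(0.75)

    def test_huge_variance_degenerates(self):
        a = self._mk([1.0, 2.0], np.eye(2))
        b = self._mk([9.0, 9.0], 1e12 * np.eye(2))
        res = est.combine_ivw(a, b)
        np.testing.assert_allclose(res.beta, a.beta, atol=1e-9)
        np.testing.assert_allclose(res.cov_beta, a.cov_beta, rtol=1e-9)

    def test_swap_invariance(self):
        rng = np.random.default_rng(2)
        q = rng.normal(size=(2, 2))
        a = self._mk([1.0, -1.0], q @ q.T + np.eye(2))
        b = self._mk([0.5, 0.5], 2 * np.eye(2))
        r1 = est.combine_ivw(a, b)
        r2 = est.combine_ivw(b, a)
        np.testing.assert_allclose(r1.beta, r2.beta, atol=1e-12)

    def test_matrix_and_elementwise_agree_when_diagonal(self):
        a = self._mk([1.0, 2.0], np.diag([1.0, 4.0]))
        b = self._mk([2.0, 0.0], np.diag([2.0, 1.0]))
        r_el = est.combine_ivw(a, b)
        r_mat = est.combine_ivw(a, b, method="matrix")
        np.testing.assert_allclose(r_el.beta, r_mat.beta, atol=1e-12)

    def test_singular_covariance_rejected(self):
        a = self._mk([1.0, 2.0], np.ones((2, 2)))
        b = self._mk([2.0, 0.0], np.eye(2))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            est.combine_ivw(a, b)


class TestDiagnostic:
    def test_zero_beta_gives_zero(self, fitted):
        main, _, calib = fitted
        res = est.fit_corrected(main, calib)
        res0 = copy.copy(res)
        res0.beta = np.zeros_like(res.beta)
        assert est.approximation_diagnostic(res0, calib, main) == 0.0

    def test_quadratic_form_value(self, fitted):
        """beta = (0,1,0,0,0) turns the diagnostic into the history variance
        itself: at the first visit that is sigma2_eps exactly."""
        main, _, calib = fitted
        res = est.fit_corrected(main, calib)
        unit = copy.copy(res)
        unit.beta = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        first = main.data.groupby("id", sort=False).head(1)
        single = Panel(first.reset_index(drop=True),
                       covariates=main.covariates)
        value = est.approximation_diagnostic(unit, calib, single)
        assert value == pytest.approx(calib.sigma2_eps, rel=1e-10)

    def test_roundtrip_with_tuned_variance(self):
        """Generator variance solved for a target diagnostic reproduces that
        target when the diagnostic is evaluated with the true coefficients."""
        cfg = sim.SimulationConfig(
            n1=400, n2=200, target_cor=None, target_diagnostic=0.4,
            beta=(-3.0, np.log(1.2), 0.5, -np.log(2.0), np.log(1.1)))
        resolved = sim.resolve_config(cfg)
        main, val = sim.generate_dataset(cfg, 77, resolved)
        calib = fit_calibration(val, corr="ar1")
        res = est.fit_corrected(main, calib)
        truth = copy.copy(res)
        truth.beta = np.asarray(cfg.beta)
        forced = copy.copy(calib)
        forced.sigma2_eps = resolved.sigma2_eps
        value = est.approximation_diagnostic(truth, forced, main)
        assert value == pytest.approx(0.4, rel=0.05)
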