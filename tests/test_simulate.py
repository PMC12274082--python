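"""Generator calibration, moments, and study-runner determinism."""

import numpy as np
import pytest

from longmec import simulate as sim

from conftest import BETA_STRONG, BETA_WEAK


class TestSolvers:
    def test_residual_variance_monotone_and_boundary(self):
        cfg = sim.SimulationConfig()
        s90 = sim.solve_residual_variance(cfg, 0.90, n_mc=50_000)
        s75 = sim.solve_residual_variance(cfg, 0.75, n_mc=50_000)
        assert 0 < s90 < s75
        # targets above the zero-noise correlation are unattainable
        with pytest.raises(ValueError, match="unattainable"):
            sim.solve_residual_variance(cfg, 0.999, n_mc=20_000)

    def test_diagnostic_variance_scaling(self):
        """Doubling beta scales the required variance by 1/4 (quadratic
        form homogeneity)."""
        cfg = sim.SimulationConfig(
            beta=(-3.0, np.log(1.2), 0.5, -np.log(2.0), np.log(1.1)),
            target_cor=None)
        s1 = sim.solve_diagnostic_variance(cfg, 0.4, n_mc=50_000)
        cfg2 = sim.SimulationConfig(
            beta=(-3.0, 2 * np.log(1.2), 0.5, -2 * np.log(2.0), np.log(1.1)),
            target_cor=None)
        s2 = sim.solve_diagnostic_variance(cfg2, 0.4, n_mc=50_000)
        assert s2 == pytest.approx(s1 / 4.0, rel=1e-6)

    def test_zero_beta_diagnostic_unattainable(self):
        cfg = sim.SimulationConfig(beta=(0.0,) * 5, target_cor=None)
        with pytest.raises(ValueError, match="unattainable"):
            sim.solve_diagnostic_variance(cfg, 0.4)


class TestSelectValidationVisit:
    @pytest.mark.parametrize("u, expected", [
        ((0.9, 0.1, 0.2, 0.3, 0.4), 5),
        ((0.05, 0.5, 0.6, 0.7, 0.8), 1),
        ((0.5, 0.5, 0.6, 0.7, 0.8), 1),  # tie: first occurrence lower rank
    ])
    def test_rank_of_first(self, u, expected):
        assert sim.select_validation_visit(u) == expected

    def test_uniform_distribution(self):
        rng = np.random.default_rng(3)
        U = rng.uniform(size=(100_000, 5))
        ranks = sim._selection_ranks(U) + 1
        freq = np.bincount(ranks, minlength=6)[1:] / len(ranks)
        np.testing.assert_allclose(freq, 0.2, atol=0.005)


@pytest.fixture(scope="module")
def big_draw():
    cfg = sim.SimulationConfig(n1=100_000, n2=10, beta=BETA_STRONG)
    resolved = sim.resolve_config(cfg)
    main, _ = sim.generate_dataset(cfg, 314, resolved)
    df = main.data
    m = cfg.n_visits
    n = df["id"].nunique()
    shape = (n, m)
    return cfg, resolved, {
        col: df[col].to_numpy(float).reshape(shape)
        for col in ("time", "C", "W", "y")}


class TestGenerator:
    def test_design_moments(self, big_draw):
        cfg, _, arr = big_draw
        C, W = arr["C"], arr["W"]
        assert C.var(axis=0) == pytest.approx(1.0, abs=0.02)
        assert W.var(axis=0) == pytest.approx(1.0, abs=0.02)
        lag1 = [np.corrcoef(C[:, j], C[:, j + 1])[0, 1] for j in range(4)]
        np.testing.assert_allclose(lag1, 0.6, atol=0.015)
        lagw = [np.corrcoef(W[:, j], W[:, j + 1])[0, 1] for j in range(4)]
        np.testing.assert_allclose(lagw, 0.2, atol=0.015)
        cross = [np.cov(C[:, j], W[:, j])[0, 1] for j in range(5)]
        np.testing.assert_allclose(cross, 0.4, atol=0.015)

    def test_entry_times(self, big_draw):
        _, _, arr = big_draw
        t = arr["time"]
        assert t[:, 0].min() >= 0 and t[:, 0].max() <= 1
        np.testing.assert_allclose(np.diff(t, axis=1), 1.0)

    def test_prevalence_near_five_percent(self, big_draw):
        _, _, arr = big_draw
        assert arr["y"].mean() == pytest.approx(0.05, abs=0.01)

    def test_outcome_lag1_correlation(self):
        """The binary outcomes achieve conditional (given-covariate) lag-1
        correlation ~0.1, the AR(1) parameter of the serial dependence."""
        from scipy.special import expit

        cfg = sim.SimulationConfig(n1=10, n2=50_000, design="ms_ivs",
                                   validation="all", beta=BETA_STRONG)
        resolved = sim.resolve_config(cfg)
        _, val = sim.generate_dataset(cfg, 3, resolved)
        m = cfg.n_visits
        df = val.data
        c = df["c"].to_numpy(float).reshape(-1, m)
        t = df["time"].to_numpy(float).reshape(-1, m)
        W = df["W"].to_numpy(float).reshape(-1, m)
        y = df["y"].to_numpy(float).reshape(-1, m)
        s = sim._cumavg_rows(t, c)
        b0, b1, b2, b3, b4 = cfg.beta
        mu = expit(b0 + b1 * s + b2 * t + b3 * s * t + b4 * W)
        e = (y - mu) / np.sqrt(mu * (1 - mu))
        lag1 = np.mean(e[:, :-1] * e[:, 1:])
        assert lag1 == pytest.approx(0.1, abs=0.02)

    def test_correlation_target_achieved(self):
        cfg = sim.SimulationConfig(n1=10, n2=50_000, design="ms_ivs",
                                   validation="all", beta=BETA_WEAK)
        resolved = sim.resolve_config(cfg)
        _, val = sim.generate_dataset(cfg, 11, resolved)
        df = val.data
        m = cfg.n_visits
        C = df["C"].to_numpy(float).reshape(-1, m)
        c = df["c"].to_numpy(float).reshape(-1, m)
        cors = [np.corrcoef(c[:, j], C[:, j])[0, 1] for j in range(m)]
        assert np.mean(cors) == pytest.approx(0.90, abs=0.01)

    def test_determinism(self, small_config, small_resolved):
        a_main, a_val = sim.generate_dataset(small_config, 9, small_resolved)
        b_main, b_val = sim.generate_dataset(small_config, 9, small_resolved)
        assert a_main.data.equals(b_main.data)
        assert a_val.data.equals(b_val.data)

    def test_single_validation_mask(self, small_config, small_resolved):
        _, val = sim.generate_dataset(small_config, 9, small_resolved)
        counts = val.data.groupby("id")["c"].apply(lambda s: s.notna().sum())
        assert (counts == 1).all()

    def test_evs_carries_no_outcome(self, small_config, small_resolved):
        _, val = sim.generate_dataset(small_config, 9, small_resolved)
        assert val.data["y"].isna().all()


class TestRunStudy:
    def test_reproducible_and_parallel_invariant(self):
        cfg = sim.SimulationConfig(n1=100, n2=60, n_reps=4, seed=5,
                                   beta=BETA_WEAK)
        s1 = sim.run_study(cfg)
        s2 = sim.run_study(cfg)
        assert s1.table.equals(s2.table)
        s3 = sim.run_study(cfg, n_jobs=2)
        assert s1.table.equals(s3.table)

    def test_null_effect_configuration(self):
        """With all outcome effects null the estimators are unbiased around
        zero and coverage is near nominal."""
        cfg = sim.SimulationConfig(
            n1=300, n2=150, n_reps=60, seed=17,
            beta=(-2.5, 0.0, 0.0, 0.0, 0.0), sigma2_eps=0.4,
            target_cor=None)
        summary = sim.run_study(cfg)
        for estimator in ("naive", "corrected"):
            b3 = summary.estimates[estimator][:, 3]
            se3 = summary.ses[estimator][:, 3]
            assert abs(b3.mean()) < 3 * b3.std(ddof=1) / np.sqrt(len(b3))
            cp = summary.table.loc[(estimator, "h_x_t"), "cp"]
            assert 0.85 <= cp <= 1.0

    def test_misspecified_calibration_inflates_bias(self):
        """Dropping C x t from the calibration model while the truth includes
        it biases the corrected interaction estimate far more than the
        correctly specified fit."""
        from longmec import estimators as est
        from longmec.calibration import fit_calibration

        cfg = sim.SimulationConfig(n1=2000, n2=500, beta=BETA_WEAK)
        resolved = sim.resolve_config(cfg)
        b3 = np.asarray(cfg.beta)[3]
        err_ok, err_bad = [], []
        for k in range(40):
            main, val = sim.generate_dataset(cfg, 700 + k, resolved)
            good = fit_calibration(val, include_interaction=True)
            bad = fit_calibration(val, include_interaction=False)
            err_ok.append(est.fit_corrected(main, good).beta[3] - b3)
            err_bad.append(est.fit_corrected(main, bad).beta[3] - b3)
        assert abs(np.mean(err_bad)) > 5 * abs(np.mean(err_ok))
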