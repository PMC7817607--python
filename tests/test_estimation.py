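"""Conditional MLE: closed forms, oracles, information matrices, inference."""

import numpy as np
import pytest

from gompcens import (
    GompertzPHParams,
    DoubleCensoredDataset,
    ModelSpec,
    FitResult,
    init_from_uncensored,
    fit_cmle,
    observed_information,
    cime_diagnostic,
    confidence_intervals,
)
from gompcens.estimate import _nll_grad, _design
from gompcens.synthetic import SyntheticConfig, generate_dataset
from tests.conftest import make_exponential_dataset, make_double_censored_exponential

SPEC0 = ModelSpec(include_age=False, include_cohort=False, include_sex=False)
SPEC_COHORT = ModelSpec(include_age=False, include_cohort=True, include_sex=False)


class TestExponentialClosedForm:
    def test_uncensored_mle(self):
        ds = DoubleCensoredDataset([1.0, 2.0, 3.0], [0, 0, 0])
        fit = fit_cmle(ds, SPEC0)
        assert fit.theta[0] == pytest.approx(np.log(3.0 / 6.0), abs=1e-8)
        assert fit.converged

    def test_unit_observed_information(self):
        # for theta1 = log a at the uncensored exponential MLE,
        # J_hat = a * ybar = 1 exactly
        ds = DoubleCensoredDataset([0.3, 1.1, 2.7, 0.9, 4.0], [0] * 5)
        fit = fit_cmle(ds, SPEC0)
        J = observed_information(ds, fit.theta, SPEC0)
        assert J[0, 0] == pytest.approx(1.0, abs=1e-7)

    def test_matches_lifelines_on_right_censored_data(self):
        from lifelines import ExponentialFitter

        ds = make_exponential_dataset(0.1, 400, r_cens=8.0, seed=3)
        fit = fit_cmle(ds, SPEC0)
        ll = ExponentialFitter().fit(ds.y, ds.delta == 0)
        assert np.exp(fit.theta[0]) == pytest.approx(1.0 / ll.lambda_, rel=1e-4)


class TestGompertzOracle:
    def test_matches_flexsurv_frozen_fit(self):
        """Right-censored Gompertz fit against a frozen flexsurvreg() result.

        The fixture is regenerated deterministically; the expected
        numbers were computed once with R flexsurv 2.3.2 on the same 80
        records (shape = age slope, rate = baseline hazard).
        """
        rng = np.random.default_rng(20240817)
        u = rng.uniform(size=80)
        b1, a, r = 0.1, 0.05, 15.0
        t = np.log1p(b1 * (-np.log1p(-u)) / a) / b1
        ds = DoubleCensoredDataset(np.minimum(t, r), np.where(t <= r, 0, 1))
        spec = ModelSpec(include_age=True, include_cohort=False, include_sex=False)
        fit = fit_cmle(ds, spec)
        assert np.exp(fit.theta[0]) == pytest.approx(0.0421321125, rel=1e-5)
        assert fit.theta[1] == pytest.approx(0.0980361165, abs=1e-6)
        assert fit.loglik == pytest.approx(-208.77454646, abs=1e-5)
        # flexsurv reports the SE of log(rate) and of shape from the same
        # observed information
        assert fit.se[0] == pytest.approx(0.26381946, rel=1e-3)
        assert fit.se[1] == pytest.approx(0.03037795, rel=1e-3)


class TestInitialization:
    def test_exponential_data_gives_exponential_start(self):
        # on genuinely exponential data the profiled age slope stays near 0
        # and the baseline start is the closed-form rate n / sum(y)
        rng = np.random.default_rng(1)
        y = rng.exponential(2.0, 2000)
        ds = DoubleCensoredDataset(y, np.zeros(2000, int))
        init = init_from_uncensored(ds)
        assert init.beta1 < 0.02
        assert np.exp(init.log_a) == pytest.approx(len(y) / y.sum(), rel=0.05)
        assert init.beta2 == (0.0,) * 5 and init.beta3 == 0.0

    def test_fallback_when_no_uncensored(self, caplog):
        ds = DoubleCensoredDataset([1.0, 2.0], [1, 1])
        init = init_from_uncensored(ds)
        assert np.exp(init.log_a) == pytest.approx(0.01)
        assert init.beta1 == pytest.approx(0.1)

    def test_profile_recovery_on_gompertz_draws(self):
        rng = np.random.default_rng(12)
        a, b1 = 0.02, 0.15
        u = rng.uniform(size=10_000)
        t = np.log1p(b1 * (-np.log1p(-u)) / a) / b1
        ds = DoubleCensoredDataset(t, np.zeros_like(t, int))
        init = init_from_uncensored(ds)
        assert np.exp(init.log_a) == pytest.approx(a, rel=0.15)
        assert init.beta1 == pytest.approx(b1, rel=0.15)


class TestInformationMatrices:
    def test_analytic_gradient_matches_finite_differences(self, ref_params):
        cfg = SyntheticConfig(n=300, theta=ref_params, cohort_weights=(1 / 6,) * 6,
                              seed=4)
        ds, _ = generate_dataset(cfg)
        spec = ModelSpec()
        X, names = _design(ds, spec)
        theta = np.array([np.log(0.01), 0.08, 0.1, -0.1, 0.05, 0.0, 0.2, -0.1])
        _, g = _nll_grad(theta, ds.y, ds.delta, X, True)
        h = 1e-6
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (
                _nll_grad(tp, ds.y, ds.delta, X, True)[0]
                - _nll_grad(tm, ds.y, ds.delta, X, True)[0]
            ) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_symmetry_and_positive_definite(self):
        ds = make_double_censored_exponential(0.3, 2000, l=1.0, r=6.0, seed=8)
        fit = fit_cmle(ds, SPEC0)
        J = observed_information(ds, fit.theta, SPEC0)
        assert np.abs(J - J.T).max() == 0.0
        assert np.linalg.eigvalsh(J).min() > 0

    def test_outer_product_information_is_psd(self, ref_params):
        cfg = SyntheticConfig(n=500, theta=ref_params, seed=6)
        ds, _ = generate_dataset(cfg)
        theta = np.array([-4.0, 0.05, 0.1, 0.1, 0.1, 0.1, 0.1, -0.1])
        _, I_hat, _ = cime_diagnostic(ds, theta)
        assert np.linalg.eigvalsh(I_hat).min() > -1e-10

    def test_misspecification_keeps_matrices_apart(self):
        # exponential fit to strongly Gompertz data: the information
        # matrix equality must fail detectably
        rng = np.random.default_rng(5)
        b1, a = 0.5, 0.01
        u = rng.uniform(size=20_000)
        t = np.log1p(b1 * (-np.log1p(-u)) / a) / b1
        ds = DoubleCensoredDataset(t, np.zeros_like(t, int))
        fit = fit_cmle(ds, SPEC0)
        _, _, rel = cime_diagnostic(ds, fit.theta, SPEC0)
        assert rel > 0.2


class TestFitBehaviour:
    def test_score_zero_and_criterion_improves_on_init(self, ref_params):
        cfg = SyntheticConfig(n=3000, theta=ref_params, seed=17)
        ds, _ = generate_dataset(cfg)
        spec = ModelSpec()
        init = init_from_uncensored(ds)
        fit = fit_cmle(ds, spec, init=init)
        assert fit.converged
        assert fit.grad_sup < 1e-6 * len(ds)
        X, _ = _design(ds, spec)
        theta0 = np.zeros(8)
        theta0[0], theta0[1] = init.log_a, init.beta1
        nll_init, _ = _nll_grad(theta0, ds.y, ds.delta, X, True)
        assert fit.loglik >= -nll_init

    def test_stratified_equals_joint_cohort_only_fit(self):
        cfg = SyntheticConfig(n=8000, seed=23)
        ds, _ = generate_dataset(cfg)
        joint = fit_cmle(ds, SPEC_COHORT)
        strat = fit_cmle(ds, ModelSpec(stratified_cohort=True))
        d_joint = dict(zip(joint.names, joint.theta))
        d_strat = dict(zip(strat.names, strat.theta))
        for name in ("log_a", "z1", "z2", "z3", "z4", "z5"):
            assert d_strat[name] == pytest.approx(d_joint[name], abs=1e-5)

    def test_cohort_slope_attenuates_when_prevalent_cases_included(self):
        """Imbalanced left-censoring across cohorts steepens the apparent
        cohort trend when prevalent cases are dropped; including them
        attenuates the slope back toward the truth."""
        cfg = SyntheticConfig(n=40_000, seed=5)
        ds, _ = generate_dataset(cfg)
        fit_in = fit_cmle(ds)
        fit_ex = fit_cmle(ds.drop_left_censored())

        def cohort_slope(fit):
            d = dict(zip(fit.names, fit.theta))
            levels = [d["z1"], d["z2"], d["z3"], 0.0, d["z4"], d["z5"]]
            return np.polyfit(np.arange(6), levels, 1)[0]

        s_in, s_ex = cohort_slope(fit_in), cohort_slope(fit_ex)
        assert s_ex > s_in > 0
        # the baseline hazard rises and the age slope dips with inclusion
        assert fit_in.theta[0] > fit_ex.theta[0]
        assert fit_in.theta[1] < fit_ex.theta[1]

    def test_monte_carlo_sd_matches_mean_estimated_se(self):
        theta = GompertzPHParams(np.log(0.005), 0.08, (0,) * 5, -0.3)
        spec = ModelSpec(include_age=True, include_cohort=False, include_sex=True)
        ests, ses = [], []
        for r in range(200):
            cfg = SyntheticConfig(n=2000, theta=theta, cohort_weights=(1 / 6,) * 6,
                                  seed=50_000 + r)
            ds, _ = generate_dataset(cfg)
            f = fit_cmle(ds, spec)
            ests.append(f.theta)
            ses.append(f.se)
        sd = np.std(ests, axis=0, ddof=1)
        mean_se = np.mean(ses, axis=0)
        np.testing.assert_allclose(sd, mean_se, rtol=0.10)


class TestIntervalsAndSerialization:
    def test_interval_width_and_level(self):
        ds = make_double_censored_exponential(0.3, 1000, l=1.0, r=6.0, seed=2)
        fit = fit_cmle(ds, SPEC0)
        ci = confidence_intervals(fit, 0.95)
        width = ci[:, 1] - ci[:, 0]
        np.testing.assert_allclose(width, 2 * 1.96 * fit.se, rtol=1e-3)
        np.testing.assert_allclose(fit.ci95, ci, rtol=1e-3)
        ci99 = confidence_intervals(fit, 0.99)
        assert np.all(ci99[:, 1] - ci99[:, 0] > width)

    def test_degenerate_se_gives_point_interval(self):
        fit = FitResult(("log_a",), np.array([-1.0]), 0.0, np.eye(1),
                        np.array([0.0]), np.array([[-1.0, -1.0]]), True, 0.0,
                        {"left": 0, "uncensored": 1, "right": 0})
        ci = confidence_intervals(fit)
        assert ci[0, 0] == ci[0, 1] == -1.0

    def test_json_round_trip(self, tmp_path):
        ds = make_double_censored_exponential(0.3, 500, l=1.0, r=6.0, seed=4)
        fit = fit_cmle(ds, SPEC0)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back.names == fit.names
        np.testing.assert_allclose(back.theta, fit.theta)
        np.testing.assert_allclose(back.se, fit.se)
        np.testing.assert_allclose(back.info, fit.info)
        assert back.converged == fit.converged
        assert back.n_used == fit.n_used
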