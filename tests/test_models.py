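"""Likelihood fitters, slope standardization and replicate summaries.

The independent oracle used throughout is a brute-force Nelder-Mead
maximization of log-likelihoods written directly with scipy.stats
densities — never the package's own likelihood code.
"""

import numpy as np
import pytest
from scipy import optimize, special, stats

from bgscale import (BetaRegression, GammaLogGLM, ResponseSpec,
                     fit_beta_regression, fit_gamma_glm,
                     generate_response_table, squeeze_unit_interval,
                     summarize_replicates)


def _oracle_gamma_loglik(theta, x, y):
    b0, b1, lognu = theta
    nu = np.exp(lognu)
    mu = np.exp(b0 + b1 * x)
    return np.sum(stats.gamma.logpdf(y, a=nu, scale=mu / nu))


def _oracle_beta_loglik(theta, x, y):
    b0, b1, logphi = theta
    phi = np.exp(logphi)
    mu = special.expit(b0 + b1 * x)
    return np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))


def _nelder_mead_max(fun, x0):
    res = optimize.minimize(lambda t: -fun(t), x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20_000, "maxfev": 20_000})
    return res.x


class TestGammaGLM:
    def test_noiseless_exponential_recovered_exactly(self):
        x = np.linspace(0.0, 400.0, 40)
        y = np.exp(1.0 + 0.01 * x)
        res = fit_gamma_glm(x, y)
        assert res.beta0 == pytest.approx(1.0, abs=1e-6)
        assert res.beta1 == pytest.approx(0.01, abs=1e-6)
        assert res.pseudo_r2() == pytest.approx(1.0, abs=1e-8)

    def test_simulation_recovery_within_3_se(self):
        spec = ResponseSpec("gamma-log", beta0=0.5, beta1=0.005,
                            shape_or_precision=10.0, n=1000, seed=31)
        t = generate_response_table(spec)
        res = fit_gamma_glm(t.x, t.y)
        assert abs(res.beta0 - 0.5) < 3 * res.bse[0]
        assert abs(res.beta1 - 0.005) < 3 * res.bse[1]
        assert abs(res.shape_ - 10.0) < 3 * res.bse[2]

    def test_oracle_equivalence_n20(self):
        t = generate_response_table(ResponseSpec("gamma-log", 0.5, 0.005, 10.0,
                                                 n=20, seed=17))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        res = fit_gamma_glm(x, y)
        theta = _nelder_mead_max(lambda th: _oracle_gamma_loglik(th, x, y),
                                 np.array([0.4, 0.004, np.log(8.0)]))
        assert res.beta0 == pytest.approx(theta[0], abs=1e-4)
        assert res.beta1 == pytest.approx(theta[1], abs=1e-4)
        assert res.shape_ == pytest.approx(np.exp(theta[2]), rel=1e-3)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        t = generate_response_table(ResponseSpec("gamma-log", 0.5, 0.005, 10.0,
                                                 n=300, seed=23))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        res = fit_gamma_glm(x, y)
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        assert res.params == pytest.approx(glm.params, abs=1e-6)

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            GammaLogGLM(np.array([1.0, -2.0, 3.0]), np.arange(3.0))

    def test_constant_predictor_flagged_not_raised(self):
        res = GammaLogGLM(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4)).fit()
        assert not res.converged
        assert res.pseudo_r2() == pytest.approx(0.0)  # intercept-only deviance

    def test_deviance_ratio_matches_hand_computation(self):
        t = generate_response_table(ResponseSpec("gamma-log", 0.5, 0.005, 10.0,
                                                 n=20, seed=29))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        res = fit_gamma_glm(x, y)
        mu = np.exp(res.beta0 + res.beta1 * x)
        dev = 2 * np.sum(-np.log(y / mu) + (y - mu) / mu)
        dev0 = 2 * np.sum(-np.log(y / y.mean()) + (y - y.mean()) / y.mean())
        assert res.pseudo_r2() == pytest.approx(1 - dev / dev0, abs=1e-10)

    def test_loglik_trace_never_decreases(self):
        t = generate_response_table(ResponseSpec("gamma-log", 0.5, 0.005, 10.0,
                                                 n=200, seed=37))
        res = fit_gamma_glm(t.x, t.y)
        tr = res.loglik_trace
        assert np.all(np.diff(tr) >= -1e-7 * (1 + np.abs(tr[1:])))


class TestBetaRegression:
    def test_simulation_recovery_within_3_se(self):
        spec = ResponseSpec("beta-logit", beta0=-1.0, beta1=0.02,
                            shape_or_precision=50.0, n=2000, x_range=(0, 100),
                            seed=41)
        t = generate_response_table(spec)
        res = fit_beta_regression(t.x, t.y)
        assert res.converged
        assert abs(res.beta0 + 1.0) < 3 * res.bse[0]
        assert abs(res.beta1 - 0.02) < 3 * res.bse[1]
        assert abs(res.precision_ - 50.0) < 3 * res.bse[2]

    def test_oracle_equivalence_n20(self):
        t = generate_response_table(ResponseSpec("beta-logit", -1.0, 0.02, 50.0,
                                                 n=20, x_range=(0, 100), seed=43))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        res = fit_beta_regression(x, y)
        theta = _nelder_mead_max(lambda th: _oracle_beta_loglik(th, x, y),
                                 np.array([-0.8, 0.015, np.log(40.0)]))
        assert res.beta0 == pytest.approx(theta[0], abs=1e-4)
        assert res.beta1 == pytest.approx(theta[1], abs=1e-4)
        assert res.precision_ == pytest.approx(np.exp(theta[2]), rel=1e-3)

    def test_matches_statsmodels_betamodel(self):
        betareg = pytest.importorskip("statsmodels.othermod.betareg")
        import statsmodels.api as sm

        t = generate_response_table(ResponseSpec("beta-logit", -1.0, 0.02, 50.0,
                                                 n=400, x_range=(0, 100), seed=47))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        res = fit_beta_regression(x, y)
        bm = betareg.BetaModel(y, sm.add_constant(x)).fit(disp=0)
        assert res.params == pytest.approx(bm.params[:2], abs=1e-5)
        # statsmodels parametrizes precision through exp(const)
        assert res.precision_ == pytest.approx(np.exp(bm.params[2]), rel=1e-4)

    def test_mle_dominates_generating_parameters(self):
        for seed in range(5):
            t = generate_response_table(ResponseSpec("beta-logit", -1.0, 0.02, 50.0,
                                                     n=150, x_range=(0, 100),
                                                     seed=seed))
            m = BetaRegression(t.y.to_numpy(), t.x.to_numpy())
            res = m.fit()
            assert res.llf >= m.loglike([-1.0, 0.02], 50.0) - 1e-8

    def test_boundary_values_rejected_with_pointer_to_squeeze(self):
        y = np.array([0.0, 0.5, 0.9])
        with pytest.raises(ValueError, match="squeeze"):
            BetaRegression(y, np.arange(3.0))

    def test_type_one_error_rate_null_slope(self):
        """Under beta1 = 0, |slope| < 3 SE in at least 95% of 200 seeds."""
        hits = 0
        for seed in range(200):
            t = generate_response_table(ResponseSpec("beta-logit", 0.5, 0.0, 30.0,
                                                     n=120, x_range=(0, 100),
                                                     seed=7000 + seed))
            res = fit_beta_regression(t.x, t.y)
            if res.converged and abs(res.beta1) < 3 * res.bse[1]:
                hits += 1
        assert hits >= 0.95 * 200

    def test_loglik_trace_never_decreases(self):
        t = generate_response_table(ResponseSpec("beta-logit", -1.0, 0.02, 50.0,
                                                 n=500, x_range=(0, 100), seed=53))
        res = fit_beta_regression(t.x, t.y)
        tr = res.loglik_trace
        assert np.all(np.diff(tr) >= -1e-7 * (1 + np.abs(tr[1:])))


class TestSqueeze:
    @pytest.mark.parametrize("y, n, expected", [
        (0.5, 17, 0.5),      # fixed point
        (0.0, 20, 0.025),
        (1.0, 20, 0.975),
    ])
    def test_known_values(self, y, n, expected):
        assert squeeze_unit_interval(y, n) == pytest.approx(expected)

    def test_order_preserving_and_interior(self):
        y = np.array([0.0, 0.2, 0.5, 0.9, 1.0])
        z = squeeze_unit_interval(y, 12)
        assert np.all(np.diff(z) > 0)
        assert np.all((z > 0) & (z < 1))


class TestStandardizedSlope:
    def _noiseless_gamma_fit(self, b0, b1):
        x = np.linspace(0.0, 300.0, 30)
        return fit_gamma_glm(x, np.exp(b0 + b1 * x)), x

    def test_gamma_formula(self):
        # b1 = 0.01, mu(x_ref) = 10, sd_y = 5 -> 0.01 * 10 / 5 = 0.02
        res, _ = self._noiseless_gamma_fit(1.0, 0.01)
        x_ref = (np.log(10.0) - res.beta0) / res.beta1
        assert res.standardized_slope(x_ref=x_ref, sd_y=5.0) == pytest.approx(0.02, rel=1e-6)

    def test_beta_formula(self):
        # b1 = 0.02, mu = 0.5, sd_y = 0.1 -> 0.02 * 0.25 / 0.1 = 0.05
        rng = np.random.default_rng(3)
        x = np.linspace(-50, 50, 400)
        mu = special.expit(0.0 + 0.02 * x)
        y = np.clip(rng.beta(mu * 500, (1 - mu) * 500), 1e-9, 1 - 1e-9)
        res = fit_beta_regression(x, y)
        slope = res.standardized_slope(x_ref=0.0, sd_y=0.1)
        mu_hat = special.expit(res.beta0)
        assert slope == pytest.approx(res.beta1 * mu_hat * (1 - mu_hat) / 0.1, rel=1e-9)
        assert slope == pytest.approx(0.05, rel=0.05)  # near the known construction

    def test_zero_slope_gives_zero(self):
        res, x = self._noiseless_gamma_fit(1.0, 0.0)
        assert res.standardized_slope(x_ref=float(x.mean()), sd_y=2.0) == \
            pytest.approx(0.0, abs=1e-10)

    def test_zero_sd_flagged_missing(self):
        res, x = self._noiseless_gamma_fit(1.0, 0.01)
        assert np.isnan(res.standardized_slope(x_ref=0.0, sd_y=0.0))

    def test_gamma_slope_invariant_to_response_rescaling(self):
        t = generate_response_table(ResponseSpec("gamma-log", 0.5, 0.005, 10.0,
                                                 n=400, seed=59))
        x, y = t.x.to_numpy(), t.y.to_numpy()
        s1 = fit_gamma_glm(x, y).standardized_slope()
        s2 = fit_gamma_glm(x, 7.3 * y).standardized_slope()
        assert s2 == pytest.approx(s1, rel=1e-8)


class _StubFit:
    """Minimal results interface for exercising the replicate summary."""

    def __init__(self, slope, r2=0.5, converged=True):
        self._slope = slope
        self._r2 = r2
        self.converged = converged

    def standardized_slope(self, x_ref=None, sd_y=None):
        return self._slope

    def pseudo_r2(self):
        return self._r2

    def predict(self, x):
        return np.full_like(np.asarray(x, dtype=float), self._slope)


class TestSummarizeReplicates:
    def test_degenerate_identical_fits(self):
        fits = [_StubFit(0.25) for _ in range(50)]
        s = summarize_replicates(fits, np.linspace(0, 1, 5))
        assert all(v == pytest.approx(0.25) for v in s.slope_percentiles.values())
        assert np.allclose(s.band_lower, s.band_upper)

    def test_linear_interpolation_percentile_convention(self):
        fits = [_StubFit(float(v)) for v in range(1, 101)]
        s = summarize_replicates(fits, np.empty(0))
        assert s.slope_percentiles[50] == pytest.approx(50.5)
        assert s.slope_percentiles[25] == pytest.approx(np.percentile(np.arange(1, 101), 25))

    def test_band_ordering_and_exclusion_counts(self):
        rng = np.random.default_rng(1)
        fits = [_StubFit(float(v)) for v in rng.normal(0, 1, 40)]
        fits += [_StubFit(0.0, converged=False), _StubFit(float("nan"))]
        s = summarize_replicates(fits, np.linspace(0, 1, 7))
        assert s.n_replicates_used == 40
        assert s.n_replicates_failed == 2
        assert np.all(s.band_lower <= s.band_median + 1e-12)
        assert np.all(s.band_median <= s.band_upper + 1e-12)

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 60)
        a = summarize_replicates([_StubFit(float(v)) for v in vals], np.empty(0))
        b = summarize_replicates([_StubFit(float(v)) for v in vals[::-1]], np.empty(0))
        assert a.slope_percentiles == pytest.approx(b.slope_percentiles)
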