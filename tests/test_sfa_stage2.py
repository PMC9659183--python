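import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tsdea import (SFADegenerateError, SFAFit, adjust_inputs, decompose_errors,
                   fit_sfa, jlms_conditional_mean)
from tsdea.sfa_stage2 import ErrorDecomposition, _ols_fit


def jlms_quad_oracle(eps, sigma, lam):
    """Brute-force posterior mean of the half-normal inefficiency:
    E[u | v + u = eps] by numerical integration of the truncated posterior.

    Integrates the joint kernel over a finite window around the posterior
    peak (normalised in log space so the quadrature never underflows); the
    location/width of the window come from completing the square, but the
    integrand itself is the raw product of the two normal kernels.
    """
    su2 = sigma ** 2 * lam ** 2 / (1.0 + lam ** 2)
    sv2 = sigma ** 2 / (1.0 + lam ** 2)
    mu_star = eps * su2 / (su2 + sv2)
    s_star = np.sqrt(su2 * sv2 / (su2 + sv2))
    u0 = max(mu_star, 0.0)

    def log_kernel(u):
        return -u ** 2 / (2 * su2) - (eps - u) ** 2 / (2 * sv2)

    ref = log_kernel(u0)

    def kernel(u):
        return np.exp(log_kernel(u) - ref)

    hi = u0 + 15.0 * s_star
    pts = [p for p in (u0,) if 0.0 < p < hi]
    num = quad(lambda u: u * kernel(u), 0, hi, points=pts, limit=400)[0]
    den = quad(kernel, 0, hi, points=pts, limit=400)[0]
    return num / den


def simulate_slack(rng, n, beta, gamma, sigma_sq, n_env=None):
    """Draws from the composed-error slack model with known truth."""
    beta = np.asarray(beta, float)
    p = len(beta) - 1 if n_env is None else n_env
    Z = rng.normal(size=(n, p))
    su = np.sqrt(gamma * sigma_sq)
    sv = np.sqrt((1.0 - gamma) * sigma_sq)
    v = rng.normal(0.0, sv, n)
    u = np.abs(rng.normal(0.0, 1.0, n)) * su
    y = beta[0] + Z @ beta[1:] + v + u
    return y, Z, u, v


class TestJLMS:
    def test_zero_residual_closed_value(self):
        # sigma_u = sigma_v = 1: sigma* = 1/sqrt(2), E = sigma* phi(0)/Phi(0)
        val = jlms_conditional_mean(0.0, np.sqrt(2.0), 1.0)
        assert val == pytest.approx(np.sqrt(2.0 / np.pi) / np.sqrt(2.0),
                                    abs=1e-12)
        assert val == pytest.approx(0.56419, abs=1e-5)

    def test_monotone_increasing_in_residual(self):
        eps = np.linspace(-6.0, 6.0, 121)
        for sigma, lam in [(0.5, 0.4), (np.sqrt(2.0), 1.0), (2.0, 3.0)]:
            vals = jlms_conditional_mean(eps, sigma, lam)
            assert np.all(np.diff(vals) > 0)
            assert np.all(vals > 0)

    def test_deep_negative_residual_matches_asymptote(self):
        # E[u|eps] -> sigma_*^2 / |mu_*| far below the frontier
        sigma, lam = np.sqrt(2.0), 1.0
        val = jlms_conditional_mean(-40.0, sigma, lam)
        mu_star = -40.0 * lam ** 2 / (1.0 + lam ** 2)
        sigma_star_sq = sigma ** 2 * lam ** 2 / (1.0 + lam ** 2) ** 2
        assert np.isfinite(val) and val > 0
        assert val == pytest.approx(sigma_star_sq / abs(mu_star), rel=1e-2)

    def test_matches_numerical_integration(self):
        for eps in (-3.0, -1.0, 0.0, 0.7, 2.5):
            for sigma in (0.5, 1.5):
                for lam in (0.4, 1.0, 2.5):
                    assert jlms_conditional_mean(eps, sigma, lam) == \
                        pytest.approx(jlms_quad_oracle(eps, sigma, lam),
                                      abs=1e-6)

    @given(eps=st.floats(-60.0, 60.0), sigma=st.floats(0.05, 20.0),
           lam=st.floats(0.02, 50.0), delta=st.floats(1e-3, 5.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_positive_finite_and_monotone_everywhere(self, eps, sigma, lam,
                                                     delta):
        lo = jlms_conditional_mean(eps, sigma, lam)
        hi = jlms_conditional_mean(eps + delta, sigma, lam)
        assert np.isfinite(lo) and lo > 0
        # strict monotonicity up to float rounding in the deep left tail,
        # where the value itself decays like sigma_*^2/|mu_*|
        assert hi >= lo * (1.0 - 1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            jlms_conditional_mean(0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            jlms_conditional_mean(0.0, 1.0, 0.0)


class TestFitSFA:
    def test_loglik_dominates_ols_start(self, rng):
        for _ in range(5):
            y, Z, _, _ = simulate_slack(rng, 150, [1.0, -2.0, 0.5], 0.6, 2.0)
            fit = fit_sfa(y, Z, compute_se=False)
            Zd = np.column_stack([np.ones(len(y)), (Z - Z.mean(0)) / Z.std(0)])
            _, _, ll_ols = _ols_fit(y, Zd)
            # equality holds only in the gamma -> 0 limit, which the logit
            # parameterization approaches but cannot reach exactly
            assert fit.log_likelihood >= ll_ols - 1e-5
            assert fit.lr_one_sided >= 0.0

    def test_parameter_recovery_median_error(self, rng):
        # panel-sized samples: median |gamma_hat - gamma| <= 0.15 and the
        # sign of every strong coefficient recovered in all replicates
        gamma, sigma_sq = 0.7, 4.0
        beta = np.array([3.0, -2.0, -1.5, 1.0])
        errs, signs = [], []
        for _ in range(60):
            y, Z, _, _ = simulate_slack(rng, 124, beta, gamma, sigma_sq)
            fit = fit_sfa(y, Z, compute_se=False)
            errs.append(abs(fit.gamma - gamma))
            signs.append(np.all(np.sign(fit.beta[1:]) == np.sign(beta[1:])))
        assert np.median(errs) <= 0.15
        assert np.mean(signs) == 1.0

    def test_degenerate_exact_fit_raises(self, rng):
        Z = rng.normal(size=(40, 2))
        y = 1.0 + Z @ np.array([2.0, -1.0])
        with pytest.raises(SFADegenerateError):
            fit_sfa(y, Z)

    def test_reports_asymptotic_se(self, rng):
        y, Z, _, _ = simulate_slack(rng, 300, [1.0, 2.0], 0.7, 4.0)
        fit = fit_sfa(y, Z)
        assert fit.beta_se is not None and np.all(fit.beta_se > 0)
        # slope recovered within 3 asymptotic standard errors
        assert abs(fit.beta[1] - 2.0) <= 3.0 * fit.beta_se[1]


class TestDecomposeErrors:
    def test_additive_reconstruction(self, rng):
        y, Z, _, _ = simulate_slack(rng, 200, [1.0, -1.0, 0.5], 0.7, 2.0)
        fit = fit_sfa(y, Z, compute_se=False)
        dec = decompose_errors(fit, y, Z)
        np.testing.assert_allclose(dec.env_effect + dec.u_hat + dec.v_hat, y,
                                   atol=1e-10)
        assert np.all(dec.u_hat > 0)

    def test_noise_recovery_correlation(self, rng):
        y, Z, u, v = simulate_slack(rng, 500, [0.0, 1.0], 0.7, 2.0)
        fit = fit_sfa(y, Z, compute_se=False)
        dec = decompose_errors(fit, y, Z)
        assert np.corrcoef(dec.v_hat, v)[0, 1] > 0.5
        assert np.corrcoef(dec.u_hat, u)[0, 1] > 0.3

    def test_gamma_zero_pure_noise_limit(self, rng):
        fit = SFAFit(input_index=0, beta=np.array([1.0, 0.5]), sigma_sq=1.0,
                     gamma=0.0, log_likelihood=0.0, lr_one_sided=0.0,
                     converged=True)
        Z = rng.normal(size=(20, 1))
        y = 1.0 + 0.5 * Z[:, 0] + rng.normal(size=20)
        with pytest.warns(UserWarning, match="gamma"):
            dec = decompose_errors(fit, y, Z)
        np.testing.assert_array_equal(dec.u_hat, 0.0)
        np.testing.assert_allclose(dec.v_hat, dec.residual)


class TestAdjustInputs:
    def _panel(self, x):
        import pandas as pd
        from tsdea import DMUPanel
        data = pd.DataFrame({
            "unit": [f"U{i}" for i in range(len(x))], "period": [1] * len(x),
            "x1": x, "y1": np.ones(len(x)), "z1": np.linspace(0.2, 0.8, len(x)),
        })
        return DMUPanel(data, ("x1",), ("y1",), ("z1",))

    @staticmethod
    def _fit():
        return SFAFit(input_index=0, beta=np.array([0.0, 1.0]), sigma_sq=1.0,
                      gamma=0.5, log_likelihood=0.0, lr_one_sided=0.0,
                      converged=True)

    def test_worked_example(self):
        # x = (10, 20), z.beta = (3, 5), v_hat = (-1, 2) -> x* = (15, 20)
        panel = self._panel([10.0, 20.0])
        dec = ErrorDecomposition(residual=np.zeros(2),
                                 u_hat=np.zeros(2),
                                 v_hat=np.array([-1.0, 2.0]),
                                 env_effect=np.array([3.0, 5.0]))
        adjusted = adjust_inputs(panel, [self._fit()], [dec])
        np.testing.assert_allclose(adjusted.inputs.ravel(), [15.0, 20.0])

    def test_identical_environment_and_luck_is_identity(self):
        panel = self._panel([10.0, 20.0, 30.0])
        dec = ErrorDecomposition(residual=np.zeros(3), u_hat=np.zeros(3),
                                 v_hat=np.full(3, 1.3),
                                 env_effect=np.full(3, 4.0))
        adjusted = adjust_inputs(panel, [self._fit()], [dec])
        np.testing.assert_array_equal(adjusted.inputs, panel.inputs)

    def test_adjustment_never_decreases_inputs(self, rng):
        panel = self._panel(rng.uniform(5.0, 50.0, 12))
        dec = ErrorDecomposition(residual=np.zeros(12), u_hat=np.zeros(12),
                                 v_hat=rng.normal(size=12),
                                 env_effect=rng.normal(size=12))
        adjusted = adjust_inputs(panel, [self._fit()], [dec])
        assert np.all(adjusted.inputs >= panel.inputs - 1e-12)
        np.testing.assert_array_equal(adjusted.outputs, panel.outputs)

    def test_mismatched_observations_rejected(self):
        panel = self._panel([10.0, 20.0])
        dec = ErrorDecomposition(residual=np.zeros(3), u_hat=np.zeros(3),
                                 v_hat=np.zeros(3), env_effect=np.zeros(3))
        with pytest.raises(ValueError):
            adjust_inputs(panel, [self._fit()], [dec])
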