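"""Posterior-predictive goodness-of-fit, imputation and density bands."""

import math

import numpy as np
import pytest
from scipy import integrate

import censmix as cm
from censmix.distributions import FULL_WINDOW, Interval
from conftest import constant_trace


@pytest.fixture(scope="module")
def single_gamma_model():
    return cm.MixtureModel((cm.DistributionSpec("gamma", (10.0, 20.0)),), (1.0,))


class TestMixtureRvs:
    def test_window_compliance(self, two_gamma_mixture):
        x = cm.mixture_rvs(two_gamma_mixture, 5000, Interval(20.0, 300.0), np.random.default_rng(0))
        assert x.min() >= 20.0 and x.max() <= 300.0

    def test_component_shares_follow_window_mass(self, two_gamma_mixture):
        """Conditional on X < 20 the draws must come almost surely from
        the low component: the exact conditional mean weights each
        component by q_j * P_j(X < 20)."""
        x = cm.mixture_rvs(two_gamma_mixture, 20_000, Interval(0.0, 20.0), np.random.default_rng(1))
        num = den = 0.0
        for q, comp in zip(two_gamma_mixture.weights, two_gamma_mixture.components):
            k, theta = comp.params
            mass = float(cm.cdf(comp, 20.0))
            part, _ = integrate.quad(
                lambda v, k=k, theta=theta: v * v ** (k - 1) * math.exp(-v / theta)
                / (math.gamma(k) * theta**k),
                0.0, 20.0,
            )
            num += q * part
            den += q * mass
        ref = num / den
        se = x.std(ddof=1) / math.sqrt(x.size)
        assert abs(x.mean() - ref) < 3 * se


class TestGof:
    def test_model_fitted_to_its_own_data_is_calibrated(self, fictive, gamma2_trace):
        res = cm.gof(gamma2_trace, fictive.censored_a, n_rep=400, seed=3)
        assert 0.01 < res.p_value < 0.99
        assert res.n_replicates == 400

    def test_gross_misfit_detected(self, fictive, single_gamma_model):
        bad = cm.MixtureModel((cm.DistributionSpec("gamma", (100.0, 20.0)),), (1.0,))
        res = cm.gof(constant_trace(bad, 100), fictive.censored_a, n_rep=100, seed=4)
        # observed data are far less likely than model replicates -> p near 0
        assert res.p_value < 0.01

    def test_tie_splitting_gives_half(self, two_gamma_mixture, fictive, monkeypatch):
        import censmix.posterior as post

        monkeypatch.setattr(post, "_simulate_replicate", lambda obs, model, rng: obs)
        res = cm.gof(constant_trace(two_gamma_mixture, 50), fictive.censored_a, n_rep=50, seed=5)
        assert res.p_value == pytest.approx(0.5)


class TestImpute:
    def test_no_unq_is_identity(self, fictive, two_gamma_mixture):
        obs = cm.ObservationSet(fictive.raw_a)
        tr = constant_trace(two_gamma_mixture, 50)
        for mode in ("random", "point"):
            out = cm.impute(tr, obs, n_draws=3, mode=mode, seed=0)
            np.testing.assert_array_equal(out.completed_datasets, np.tile(obs.values, (out.completed_datasets.shape[0], 1)))

    def test_bounds_respected_in_all_cells(self, fictive, gamma2_trace):
        obs = fictive.censored_b  # LDL = 20 and UDL = 300
        out = cm.impute(gamma2_trace, obs, n_draws=40, seed=1)
        low = obs.values == -math.inf
        high = obs.values == math.inf
        assert np.all(out.completed_datasets[:, low] < 20.0)
        assert np.all(out.completed_datasets[:, low] > 0.0)
        assert np.all(out.completed_datasets[:, high] > 300.0)
        untouched = ~(low | high)
        assert np.all(out.completed_datasets[:, untouched] == obs.values[untouched])

    def test_conditional_mean_matches_quadrature_oracle(self, single_gamma_model):
        """Imputed below-LDL draws at fixed gamma(10,20), LDL=100 must
        average to E[X | X < 100] = 86.058 (quadrature oracle)."""
        rng = np.random.default_rng(6)
        raw = rng.gamma(10.0, 20.0, size=400)
        obs = cm.censor(raw, Interval(100.0, math.inf))
        assert obs.n_unq > 10
        tr = constant_trace(single_gamma_model, 200)
        out = cm.impute(tr, obs, n_draws=300, seed=7)
        imputed = out.completed_datasets[:, obs.unq_mask].ravel()
        se = imputed.std(ddof=1) / math.sqrt(imputed.size)
        assert abs(imputed.mean() - 86.05783549166271) < 3 * se

    def test_point_mode_matches_random_mode_average(self, single_gamma_model):
        rng = np.random.default_rng(8)
        raw = rng.gamma(10.0, 20.0, size=300)
        obs = cm.censor(raw, Interval(100.0, math.inf))
        tr = constant_trace(single_gamma_model, 200)
        point = cm.impute(tr, obs, mode="point", seed=9)
        rand = cm.impute(tr, obs, n_draws=400, mode="random", seed=9)
        cell = int(np.flatnonzero(obs.unq_mask)[0])
        draws = rand.completed_datasets[:, cell]
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert point.completed_datasets[0, cell] == pytest.approx(draws.mean(), abs=3 * se)

    def test_impute_without_censored_unq_on_truncated_rows(self, fictive, gamma2_trace):
        out = cm.impute(gamma2_trace, fictive.truncated_a, n_draws=2, seed=0)
        np.testing.assert_array_equal(out.completed_datasets[0], fictive.truncated_a.values)

    def test_unknown_mode_rejected(self, fictive, gamma2_trace):
        with pytest.raises(ValueError):
            cm.impute(gamma2_trace, fictive.censored_a, mode="typo")


class TestPredictiveBand:
    def test_single_iteration_collapses_to_density(self, two_gamma_mixture):
        grid = np.linspace(1.0, 500.0, 60)
        tr = constant_trace(two_gamma_mixture, 1)
        band = cm.predictive_band(tr, grid, quantiles=(0.025, 0.975))
        dens = cm.mixture_density(two_gamma_mixture, grid, FULL_WINDOW)
        np.testing.assert_allclose(band["mean"], dens, rtol=1e-10)
        np.testing.assert_allclose(band["q0.025"], band["q0.975"], rtol=1e-10)

    def test_quantile_bands_nested(self, gamma2_trace):
        grid = np.linspace(1.0, 500.0, 40)
        band = cm.predictive_band(tr := gamma2_trace, grid, quantiles=(0.025, 0.25, 0.75, 0.975), n_iter=200, seed=0)
        assert np.all(band["q0.25"] >= band["q0.025"] - 1e-12)
        assert np.all(band["q0.75"] <= band["q0.975"] + 1e-12)

    def test_mean_density_integral_matches_quantified_mass(self, fictive, gamma2_trace):
        grid = np.linspace(20.0, 2000.0, 2000)
        band = cm.predictive_band(gamma2_trace, grid, n_iter=150, seed=1)
        integral = np.trapezoid(band["mean"], grid)
        p_lu = []
        for i in range(0, gamma2_trace.posterior_free().shape[0], 10):
            model = gamma2_trace.model_at(i)
            p_lu.append(cm.censoring_probs(model, Interval(20.0, math.inf))[1])
        assert integral == pytest.approx(float(np.mean(p_lu)), abs=0.01)
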