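"""Censored/truncated mixture likelihood checks.

The central identity: for a censored stratum, the conditional
formulation used here — truncated densities for quantified values plus a
multinomial term for the (below, inside, above) counts — equals the
textbook censored likelihood sum log f(x) + nLDL log F(L) +
nUDL log S(U) up to the multinomial coefficient, a constant in the
parameters: the (F(U) - F(L))^nLU window factor cancels against
pLU^nLU.
"""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import censmix as cm
from censmix.distributions import FULL_WINDOW, Interval


def make_model(*specs, weights=None):
    specs = tuple(specs)
    weights = weights or tuple([1.0 / len(specs)] * len(specs))
    return cm.MixtureModel(specs, weights)


class TestMixtureDensity:
    def test_single_component_equals_truncated_pdf(self):
        spec = cm.DistributionSpec("gamma", (10.0, 20.0))
        model = make_model(spec)
        w = Interval(20.0, math.inf)
        assert cm.mixture_density(model, 100.0, w) == pytest.approx(
            cm.truncated_pdf(spec, 100.0, w), rel=1e-12
        )

    def test_equal_weight_identical_components_degenerate(self):
        spec = cm.DistributionSpec("lognormal", (4.0, 0.8))
        single = make_model(spec)
        double = make_model(spec, spec)
        w = Interval(10.0, 500.0)
        assert cm.mixture_density(double, 50.0, w) == pytest.approx(
            cm.mixture_density(single, 50.0, w), rel=1e-12
        )

    def test_two_gamma_mixture_matches_quadrature_oracle(self, two_gamma_mixture):
        # average of the two per-component quadrature-normalized densities
        got = cm.mixture_density(two_gamma_mixture, 100.0, Interval(20.0, math.inf))
        assert got == pytest.approx(0.0019050402146951232, rel=1e-8)


class TestCensoringProbs:
    def test_no_limits(self, two_gamma_mixture):
        assert cm.censoring_probs(two_gamma_mixture, FULL_WINDOW) == (0.0, 1.0, 0.0)

    def test_pldl_matches_quadrature_oracle(self):
        model = make_model(cm.DistributionSpec("gamma", (10.0, 20.0)))
        p_ldl, p_lu, p_udl = cm.censoring_probs(model, Interval(20.0, math.inf))
        assert p_ldl == pytest.approx(1.1142547833872071e-07, rel=1e-8)
        assert p_udl == 0.0

    @pytest.mark.parametrize("window", [Interval(20, 300), Interval(5, math.inf), Interval(0, 90)])
    def test_partition_sums_to_one(self, two_gamma_mixture, window):
        probs = cm.censoring_probs(two_gamma_mixture, window)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= p <= 1.0 for p in probs)


class TestMultinomialLogmass:
    def test_certain_outcome(self):
        assert cm.multinomial_logmass((0, 17, 0), (0.0, 1.0, 0.0)) == 0.0

    def test_two_category_enumeration(self):
        got = cm.multinomial_logmass((1, 1, 0), (0.5, 0.5, 0.0))
        assert got == pytest.approx(math.log(2 * 0.25), rel=1e-12)

    def test_matches_exact_factorial_oracle(self):
        # 10!/(3!5!2!) * .2^3 * .7^5 * .1^2, computed with integer factorials
        got = cm.multinomial_logmass((3, 5, 2), (0.2, 0.7, 0.1))
        assert got == pytest.approx(-3.3848444624785845, rel=1e-12)

    def test_impossible_count_gives_neg_inf(self):
        assert cm.multinomial_logmass((1, 5, 0), (0.0, 1.0, 0.0)) == -math.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cm.multinomial_logmass((-1, 1, 0), (0.5, 0.5, 0.0))
        with pytest.raises(ValueError):
            cm.multinomial_logmass((1, 1, 0), (0.9, 0.9, 0.0))


def censored_loglik_oracle(values, n_ldl, n_udl, ldl, udl, k, theta):
    """Textbook censored-gamma likelihood, written with scipy.stats only."""
    ll = float(np.sum(stats.gamma.logpdf(values, k, scale=theta)))
    if n_ldl:
        ll += n_ldl * stats.gamma.logcdf(ldl, k, scale=theta)
    if n_udl:
        ll += n_udl * stats.gamma.logsf(udl, k, scale=theta)
    n = len(values) + n_ldl + n_udl
    coeff = gammaln(n + 1) - gammaln(n_ldl + 1) - gammaln(n_udl + 1) - gammaln(len(values) + 1)
    return ll, float(coeff)


class TestLoglik:
    def test_fully_quantified_censored_equals_density_sum(self, two_gamma_mixture):
        rng = np.random.default_rng(5)
        x = rng.gamma(10.0, 20.0, size=40)
        obs = cm.ObservationSet(x)  # no limits, censored
        expected = float(np.sum(np.log(cm.mixture_density(two_gamma_mixture, x, FULL_WINDOW))))
        assert cm.loglik(obs, two_gamma_mixture) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_censored_identity_on_random_instances(self, seed):
        """Conditional-plus-multinomial equals the standard censored
        formulation plus the multinomial coefficient, to 1e-8."""
        rng = np.random.default_rng(seed)
        k = rng.uniform(1.0, 15.0)
        theta = rng.uniform(2.0, 40.0)
        raw = rng.gamma(k, theta, size=60)
        ldl = np.quantile(raw, rng.uniform(0.05, 0.4))
        udl = np.quantile(raw, rng.uniform(0.6, 0.95))
        obs = cm.censor(raw, Interval(ldl, udl))
        model = make_model(cm.DistributionSpec("gamma", (k, theta)))
        quantified = raw[(raw >= ldl) & (raw <= udl)]
        n_ldl = int(np.sum(raw < ldl))
        n_udl = int(np.sum(raw > udl))
        oracle, coeff = censored_loglik_oracle(quantified, n_ldl, n_udl, ldl, udl, k, theta)
        assert cm.loglik(obs, model) == pytest.approx(oracle + coeff, abs=1e-8)

    def test_multinomial_coefficient_offset_is_constant_in_theta(self):
        rng = np.random.default_rng(99)
        raw = rng.gamma(8.0, 10.0, size=80)
        obs = cm.censor(raw, Interval(40.0, 160.0))
        quantified = raw[(raw >= 40.0) & (raw <= 160.0)]
        n_ldl, n_udl = int(np.sum(raw < 40.0)), int(np.sum(raw > 160.0))
        offsets = []
        for k, theta in [(8.0, 10.0), (5.0, 18.0), (12.0, 6.0)]:
            model = make_model(cm.DistributionSpec("gamma", (k, theta)))
            oracle, coeff = censored_loglik_oracle(quantified, n_ldl, n_udl, 40.0, 160.0, k, theta)
            offsets.append(cm.loglik(obs, model) - oracle)
            assert offsets[-1] == pytest.approx(coeff, abs=1e-8)
        assert max(offsets) - min(offsets) < 1e-8

    def test_duplicate_component_with_split_weight_is_invariant(self, fictive):
        g1 = cm.DistributionSpec("gamma", (10.0, 20.0))
        g2 = cm.DistributionSpec("gamma", (5.0, 10.0))
        base = cm.MixtureModel((g1, g2), (0.5, 0.5))
        split = cm.MixtureModel((g1, g2, g2), (0.5, 0.3, 0.2))
        assert cm.loglik(fictive.censored_a, split) == pytest.approx(
            cm.loglik(fictive.censored_a, base), rel=1e-12
        )

    def test_censored_minus_truncated_is_multinomial_term(self, fictive, two_gamma_mixture):
        cens = cm.loglik(fictive.censored_a, two_gamma_mixture)
        trunc = cm.loglik(fictive.truncated_a, two_gamma_mixture)
        s = fictive.censored_a.strata()[0]
        probs = cm.censoring_probs(two_gamma_mixture, s.window)
        term = cm.multinomial_logmass((s.n_ldl, s.n_quantified, s.n_udl), probs)
        assert cens - trunc == pytest.approx(term, rel=1e-10)

    def test_empty_observation_set_rejected(self):
        with pytest.raises(ValueError):
            cm.ObservationSet([])

    def test_row_validation(self):
        with pytest.raises(ValueError, match="row 2"):
            cm.ObservationSet([50.0, 5.0], ldl=20.0)
        with pytest.raises(ValueError, match="truncated"):
            cm.ObservationSet([-math.inf], ldl=20.0, cut="truncated")

    def test_all_unq_censored_stratum_allowed(self):
        obs = cm.ObservationSet([-math.inf, -math.inf], ldl=20.0)
        model = make_model(cm.DistributionSpec("gamma", (5.0, 10.0)))
        assert math.isfinite(cm.loglik(obs, model))
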