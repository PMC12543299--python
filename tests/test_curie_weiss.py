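"""Curie-Weiss model: density, normalizing constant, conditionals,
marginals, exact sampling, and the (mu, sigma) posterior update."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logsumexp

from mlggm.curie_weiss import (
    CWTuning,
    GroupPrior,
    GroupState,
    cw_conditional_logodds,
    cw_conditional_logodds_all,
    cw_log_pmf,
    cw_log_z,
    cw_marginal_probs,
    cw_sample,
    cw_update_params,
)
from mlggm.curie_weiss import _log_z_count_dp, _log_z_quadrature
from mlggm.netcore import EdgeSpace


def softplus(x):
    return np.logaddexp(0.0, x)


def enumerate_states(E):
    return np.array(list(itertools.product([0, 1], repeat=E)), dtype=float)


def brute_log_weights(mu, sigma):
    states = enumerate_states(mu.size)
    return states, states @ mu + sigma / mu.size * states.sum(axis=1) ** 2


@pytest.fixture(params=[(3, 0.0), (3, 1.3), (5, 0.8)], ids=lambda p: f"P{p[0]}s{p[1]}")
def random_state(request):
    P, sigma = request.param
    space = EdgeSpace(P)
    mu = np.random.default_rng(P).uniform(-2, 2, space.E)
    return GroupState(mu, sigma, space)


class TestPmfAndLogZ:
    def test_uniform_case(self):
        space = EdgeSpace(3)  # E = 3
        state = GroupState(np.zeros(3), 0.0, space)
        assert np.isclose(cw_log_z(state), np.log(8.0))
        for gamma in enumerate_states(3):
            assert np.isclose(cw_log_pmf(gamma, state), np.log(1 / 8))

    def test_sigma_zero_is_independent_bernoulli(self):
        space = EdgeSpace(3)
        mu = np.array([0.7, -1.2, 2.0])
        state = GroupState(mu, 0.0, space)
        for gamma in enumerate_states(3):
            expect = (gamma * mu - softplus(mu)).sum()
            assert np.isclose(cw_log_pmf(gamma, state), expect)

    def test_softplus_values_at_independence(self):
        mu = np.array([5.0, -5.0])
        assert np.isclose(
            _log_z_count_dp(mu, 0.0), softplus(5.0) + softplus(-5.0)
        )
        assert np.isclose(
            _log_z_quadrature(mu, 0.0, 64), softplus(5.0) + softplus(-5.0)
        )

    def test_pmf_matches_enumeration(self, random_state):
        states, logw = brute_log_weights(random_state.mu, random_state.sigma)
        lz = logsumexp(logw)
        for row, lw in zip(states[::7], logw[::7]):
            assert np.isclose(cw_log_pmf(row, random_state), lw - lz, atol=1e-10)

    def test_pmf_normalizes(self, random_state):
        states, _ = brute_log_weights(random_state.mu, random_state.sigma)
        lz = cw_log_z(random_state)
        total = sum(np.exp(cw_log_pmf(row, random_state, log_z=lz)) for row in states)
        assert np.isclose(total, 1.0, atol=1e-10)

    def test_count_dp_matches_enumeration(self, random_state):
        _, logw = brute_log_weights(random_state.mu, random_state.sigma)
        assert np.isclose(cw_log_z(random_state, "count_dp"), logsumexp(logw))

    @pytest.mark.parametrize("sigma", [0.0, 0.1, 0.5, 2.0])
    def test_methods_agree_at_large_E(self, sigma):
        space = EdgeSpace(20)  # E = 190
        mu = np.random.default_rng(3).uniform(-2, 2, space.E)
        state = GroupState(mu, sigma, space)
        a = cw_log_z(state, "count_dp")
        b = cw_log_z(state, "quadrature")
        assert np.isclose(a, b, rtol=1e-8)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            GroupState(np.zeros(3), -0.5, EdgeSpace(3))

    def test_dimension_mismatch(self):
        state = GroupState(np.zeros(3), 0.0, EdgeSpace(3))
        with pytest.raises(ValueError):
            cw_log_pmf(np.array([0, 1]), state)


class TestConditionals:
    def test_sigma_zero_reduces_to_mu(self):
        space = EdgeSpace(3)
        mu = np.array([0.3, -0.7, 1.1])
        state = GroupState(mu, 0.0, space)
        gamma = np.array([1, 0, 1], dtype=np.uint8)
        for e in range(3):
            assert np.isclose(cw_conditional_logodds(e + 1, gamma, state), mu[e])

    def test_matches_enumeration_logodds(self):
        space = EdgeSpace(5)  # E = 10
        rng = np.random.default_rng(7)
        mu = rng.uniform(-1.5, 1.5, space.E)
        state = GroupState(mu, 0.9, space)
        states, logw = brute_log_weights(mu, 0.9)
        lz = logsumexp(logw)
        gamma = rng.integers(0, 2, space.E).astype(np.uint8)
        for e in range(space.E):
            g1, g0 = gamma.copy(), gamma.copy()
            g1[e], g0[e] = 1, 0
            lp1 = cw_log_pmf(g1, state, log_z=lz)
            lp0 = cw_log_pmf(g0, state, log_z=lz)
            assert np.isclose(
                cw_conditional_logodds(e + 1, gamma, state), lp1 - lp0, atol=1e-10
            )

    def test_monotone_in_neighbor_count(self):
        space = EdgeSpace(4)
        state = GroupState(np.zeros(space.E), 0.8, space)
        all_on = np.ones(space.E, np.uint8)
        all_off = np.zeros(space.E, np.uint8)
        assert cw_conditional_logodds(1, all_on, state) > cw_conditional_logodds(
            1, all_off, state
        )

    def test_vectorized_matches_scalar(self):
        space = EdgeSpace(4)
        rng = np.random.default_rng(0)
        state = GroupState(rng.normal(size=space.E), 0.5, space)
        gamma = rng.integers(0, 2, space.E).astype(np.uint8)
        vec = cw_conditional_logodds_all(gamma, state.mu, state.sigma)
        for e in range(space.E):
            assert np.isclose(vec[e], cw_conditional_logodds(e + 1, gamma, state))


class TestMarginals:
    def test_sigma_zero_is_logistic(self):
        space = EdgeSpace(4)
        mu = np.linspace(-2, 2, space.E)
        state = GroupState(mu, 0.0, space)
        assert np.allclose(cw_marginal_probs(state), expit(mu))

    def test_zero_mu_marginals_exchangeable_and_ferromagnetic(self):
        # with mu = 0 all edges are exchangeable; the squared-count
        # interaction favors configurations with more edges, so the common
        # marginal exceeds 1/2 (enumeration-checked at E = 6)
        space = EdgeSpace(4)
        state = GroupState(np.zeros(space.E), 0.7, space)
        probs = cw_marginal_probs(state)
        states, logw = brute_log_weights(state.mu, state.sigma)
        expect = np.exp(logw - logsumexp(logw)) @ states
        assert np.allclose(probs, probs[0])
        assert probs[0] > 0.5
        assert np.allclose(probs, expect, atol=1e-9)

    def test_matches_enumeration(self):
        space = EdgeSpace(5)  # E = 10, 1024 states
        mu = np.random.default_rng(11).uniform(-2, 2, space.E)
        state = GroupState(mu, 1.1, space)
        states, logw = brute_log_weights(mu, 1.1)
        probs = np.exp(logw - logsumexp(logw))
        expect = probs @ states
        assert np.allclose(cw_marginal_probs(state), expect, atol=1e-8)


class TestSampling:
    def test_fixed_seed_reproducible(self):
        space = EdgeSpace(5)
        state = GroupState(np.linspace(-1, 1, space.E), 0.6, space)
        a = cw_sample(state, 50, np.random.default_rng(5))
        b = cw_sample(state, 50, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_independent_case_frequencies(self):
        space = EdgeSpace(5)
        state = GroupState(np.zeros(space.E), 0.0, space)
        draws = cw_sample(state, 10_000, np.random.default_rng(6))
        assert np.abs(draws.mean(axis=0) - 0.5).max() < 0.02

    def test_frequencies_match_enumerated_marginals(self):
        space = EdgeSpace(5)  # E = 10
        mu = np.random.default_rng(13).uniform(-1.5, 1.5, space.E)
        state = GroupState(mu, 1.0, space)
        states, logw = brute_log_weights(mu, 1.0)
        probs = np.exp(logw - logsumexp(logw))
        marg = probs @ states
        n = 50_000
        freq = cw_sample(state, n, np.random.default_rng(14)).mean(axis=0)
        se = np.sqrt(marg * (1 - marg) / n)
        assert (np.abs(freq - marg) < 3 * se + 1e-4).all()


class TestParamUpdate:
    def test_acceptance_rates_in_band_after_adaptation(self):
        space = EdgeSpace(5)
        rng = np.random.default_rng(21)
        truth = GroupState(rng.normal(0, 1, space.E), 0.5, space)
        gammas = cw_sample(truth, 100, rng)
        state = GroupState(np.zeros(space.E), 0.1, space)
        tuning = CWTuning.init(space.E)
        prior = GroupPrior()
        for it in range(800):
            tuning.adapt = it < 400
            if it == 400:
                tuning.reset_counters()
            state = cw_update_params(gammas, state, prior, rng, tuning)
        rates = tuning.acceptance_rates
        assert 0.1 < rates["mu"] < 0.7
        assert 0.1 < rates["sigma"] < 0.7

    def test_sigma_restarts_from_zero(self):
        space = EdgeSpace(3)
        gammas = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.uint8)
        state = GroupState(np.zeros(3), 0.0, space)
        out = cw_update_params(
            gammas, state, GroupPrior(), np.random.default_rng(0), CWTuning.init(3)
        )
        assert out.sigma > 0
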