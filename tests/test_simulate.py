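"""Generative pipeline: group graph, main effects, G-Wishart precisions,
time series, and the full study (including the mixture scenario)."""

import numpy as np
import pytest
from scipy import stats

from mlggm.curie_weiss import GroupState, cw_marginal_probs, cw_sample
from mlggm.ggm import partial_correlations
from mlggm.netcore import EdgeSpace
from mlggm.simulate import (
    SimulationConfig,
    flip_edges,
    sample_gwishart,
    simulate_group_graph,
    simulate_mu,
    simulate_participant_data,
    simulate_study,
)


class TestGroupGraph:
    def test_zero_density_is_empty(self):
        g = simulate_group_graph(10, 0.0, np.random.default_rng(0))
        assert g.sum() == 0

    def test_density_matches_binomial_mean(self):
        rng = np.random.default_rng(1)
        counts = [simulate_group_graph(40, 0.16, rng).sum() for _ in range(400)]
        # E = 780, expectation 124.8, binomial sd ~ 10.2
        assert np.abs(np.mean(counts) - 124.8) < 3 * 10.24 / np.sqrt(400)

    def test_seed_reproducibility(self):
        a = simulate_group_graph(12, 0.3, np.random.default_rng(5))
        b = simulate_group_graph(12, 0.3, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestMu:
    CFG = SimulationConfig(P=5, N=4, T=50)

    def test_rho_zero_gives_zero_vector(self):
        g = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        mu = simulate_mu(g, 0.0, self.CFG, np.random.default_rng(0))
        assert (mu == 0).all()

    def test_signs_follow_group_graph(self):
        rng = np.random.default_rng(1)
        g = np.tile([1, 0], 50)
        mu = simulate_mu(g, 100.0, self.CFG, rng)
        assert (mu[g == 1] > 0).all() and (mu[g == 0] < 0).all()

    def test_truncated_normal_moments_at_full_homogeneity(self):
        rng = np.random.default_rng(2)
        g = np.ones(100_000, dtype=np.uint8)
        mu = simulate_mu(g, 100.0, self.CFG, rng)
        a = (0 - 2.73) / 2.33
        expect = stats.truncnorm.mean(a, np.inf, loc=2.73, scale=2.33)
        sd = stats.truncnorm.std(a, np.inf, loc=2.73, scale=2.33)
        assert np.abs(mu.mean() - expect) < 3 * sd / np.sqrt(mu.size)

    def test_rho_scales_both_location_and_scale(self):
        rng = np.random.default_rng(3)
        g = np.ones(50_000, dtype=np.uint8)
        mu30 = simulate_mu(g, 30.0, self.CFG, rng)
        a = (0 - 2.73 * 0.3) / (2.33 * 0.3)
        expect = stats.truncnorm.mean(a, np.inf, loc=2.73 * 0.3, scale=2.33 * 0.3)
        assert np.abs(mu30.mean() - expect) < 0.01


class TestFlipEdges:
    def test_exact_count_and_involution(self):
        rng = np.random.default_rng(4)
        g = (np.random.default_rng(5).random(200) < 0.3).astype(np.uint8)
        g2, flipped = flip_edges(g, 0.2, rng)
        assert flipped.size == 40
        assert (g2 != g).sum() == 40
        g3 = g2.copy()
        g3[flipped] ^= 1
        assert np.array_equal(g3, g)


def _chain_graph(space):
    """Path graph 1-2-3-4 on P=4 (a decomposable graph)."""
    g = np.zeros(space.E, np.uint8)
    from mlggm.netcore import edge_index

    for i in range(1, space.P):
        g[edge_index(i, i + 1, space) - 1] = 1
    return g


def _gwishart_chain_oracle(space, g, df, n, rng):
    """Synthetic independent G-Wishart sampler for a decomposable graph.

    For a decomposable graph under a perfect elimination order with
    identity scale, the upper Cholesky factor Phi of Omega = Phi' Phi has
    independent free elements: Phi_ii^2 ~ chi2(df + nu_i) with nu_i the
    number of later neighbors of node i, Phi_ij ~ N(0, 1) at edges i < j,
    and each non-edge entry completed as
    Phi_ij = -sum_{k<i} Phi_ki Phi_kj / Phi_ii (zero when i = 1).
    """
    P = space.P
    adj = np.zeros((P, P), bool)
    adj[space.rows, space.cols] = g == 1
    adj |= adj.T
    nu = [int(adj[i, i + 1 :].sum()) for i in range(P)]
    out = np.empty((n, P, P))
    for s in range(n):
        Phi = np.zeros((P, P))
        for i in range(P):
            Phi[i, i] = np.sqrt(rng.chisquare(df + nu[i]))
            for j in range(i + 1, P):
                if adj[i, j]:
                    Phi[i, j] = rng.standard_normal()
                elif i == 0:
                    Phi[i, j] = 0.0
                else:
                    Phi[i, j] = -(Phi[:i, i] @ Phi[:i, j]) / Phi[i, i]
        out[s] = Phi.T @ Phi
    return out


class TestGWishart:
    def test_empty_graph_gives_chi2_diagonal(self):
        space = EdgeSpace(4)
        rng = np.random.default_rng(6)
        g = np.zeros(space.E, np.uint8)
        draws = np.array(
            [sample_gwishart(g, space, 3.0, rng) for _ in range(1500)]
        )
        off = draws[:, space.rows, space.cols]
        assert np.abs(off).max() == 0.0
        ks = stats.kstest(draws[:, 0, 0], stats.chi2(3).cdf)
        assert ks.pvalue > 0.001

    def test_complete_graph_matches_wishart_mean(self):
        space = EdgeSpace(4)
        rng = np.random.default_rng(7)
        g = np.ones(space.E, np.uint8)
        draws = np.array(
            [sample_gwishart(g, space, 3.0, rng) for _ in range(1500)]
        )
        # complete graph: ordinary Wishart with df + P - 1 = 6, scale I
        assert np.allclose(draws.mean(axis=0), 6.0 * np.eye(4), atol=0.35)

    def test_chain_graph_matches_cholesky_oracle(self):
        space = EdgeSpace(4)
        g = _chain_graph(space)
        rng = np.random.default_rng(8)
        mine = np.array([sample_gwishart(g, space, 3.0, rng) for _ in range(4000)])
        oracle = _gwishart_chain_oracle(space, g, 3.0, 4000, np.random.default_rng(9))
        for i, j in [(0, 0), (1, 1), (0, 1), (1, 2), (2, 3)]:
            m, o = mine[:, i, j], oracle[:, i, j]
            se = np.sqrt(m.var() / m.size + o.var() / o.size)
            assert np.abs(m.mean() - o.mean()) < 4 * se, (i, j)

    def test_support_and_pd_invariant(self):
        space = EdgeSpace(7)
        rng = np.random.default_rng(10)
        for _ in range(10):
            g = (rng.random(space.E) < 0.3).astype(np.uint8)
            Om = sample_gwishart(g, space, 3.0, rng)
            pc = partial_correlations(Om, space)
            assert np.abs(pc[g == 0]).max(initial=0.0) < 1e-6
            assert np.linalg.eigvalsh(Om).min() > 0

    def test_low_df_rejected(self):
        with pytest.raises(ValueError):
            sample_gwishart(
                np.zeros(6, np.uint8), EdgeSpace(4), 2.0, np.random.default_rng(0)
            )


class TestParticipantData:
    def test_identity_precision_covariance(self):
        X = simulate_participant_data(np.eye(5), 10_000, np.random.default_rng(11))
        cov = np.cov(X.T)
        assert np.abs(cov - np.eye(5)).max() < 0.05

    def test_correlation_sign_opposes_precision_offdiagonal(self):
        Om = np.array([[1.0, 0.4], [0.4, 1.0]])
        X = simulate_participant_data(Om, 5000, np.random.default_rng(12))
        assert np.corrcoef(X.T)[0, 1] < 0

    def test_seed_reproducibility(self):
        a = simulate_participant_data(np.eye(3), 20, np.random.default_rng(13))
        b = simulate_participant_data(np.eye(3), 20, np.random.default_rng(13))
        assert np.array_equal(a, b)


class TestStudy:
    def test_shapes_and_truth_consistency(self):
        cfg = SimulationConfig(P=10, N=6, T=40, rho=30.0, seed=14)
        truth = simulate_study(cfg)
        assert truth.individual_graphs.shape == (6, 45)
        assert len(truth.precisions) == 6 and len(truth.timeseries) == 6
        assert all(x.shape == (40, 10) for x in truth.timeseries)
        for n in range(6):
            pc = partial_correlations(truth.precisions[n], truth.space)
            absent = truth.individual_graphs[n] == 0
            assert np.abs(pc[absent]).max(initial=0.0) < 1e-6

    def test_mixture_split_and_flip_fraction(self):
        cfg = SimulationConfig(
            P=10, N=10, T=30, rho=100.0, seed=15,
            mixture=True, mixture_sizes=(8, 2),
        )
        truth = simulate_study(cfg)
        E = truth.space.E
        assert (truth.group_graph_2 != truth.group_graph).sum() == round(0.2 * E)
        assert list(np.bincount(truth.labels)) == [8, 2]

    def test_individual_graph_frequencies_match_model_marginals(self):
        space = EdgeSpace(5)
        rng = np.random.default_rng(16)
        cfg = SimulationConfig(P=5, N=4, T=10)
        g = simulate_group_graph(5, 0.4, rng)
        mu = simulate_mu(g, 50.0, cfg, rng)
        state = GroupState(mu, 0.1, space)
        n = 20_000
        freq = cw_sample(state, n, rng).mean(axis=0)
        marg = cw_marginal_probs(state)
        se = np.sqrt(marg * (1 - marg) / n)
        assert (np.abs(freq - marg) < 3 * se + 1e-3).all()

    def test_rho_zero_graphs_are_fair_coins(self):
        cfg = SimulationConfig(P=8, N=60, T=10, rho=0.0, sigma=0.0, seed=17)
        truth = simulate_study(cfg)
        freq = truth.individual_graphs.mean()
        n = truth.individual_graphs.size
        assert np.abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho=120.0)
        with pytest.raises(ValueError):
            SimulationConfig(density=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(N=5, mixture=True, mixture_sizes=(80, 20))
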