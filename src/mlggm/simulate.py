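"""Generative pipeline for multilevel network studies.

The simulator mirrors the model itself: a group graph is drawn edge-wise
Bernoulli(density); each edge's Curie-Weiss main effect mu_e is drawn from
a sign-truncated normal (positive for group-present edges, negative for
group-absent ones) whose location and scale shrink linearly with the
homogeneity percentage rho; individual graphs are exact Curie-Weiss draws;
each participant's precision matrix comes from a G-Wishart distribution
restricted to their graph; and the observed series are i.i.d. multivariate
normal draws with that precision.

The truncated-normal defaults (+2.73 / 2.33 for present edges, -3.16 /
3.35 for absent ones at rho = 100) correspond to the main-effect posterior
estimated on a large resting-state fMRI cohort, so rho = 100 emulates
"as homogeneous as a real healthy population" while rho = 0 gives fully
independent participants (mu = 0, every edge a coin flip).

A mixture option generates the misspecification scenario: a second group
graph obtained by flipping a fraction of the edges, with participants
split between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curie_weiss import GroupState, cw_sample
from .netcore import EdgeSpace

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_group_graph",
    "simulate_mu",
    "flip_edges",
    "sample_gwishart",
    "simulate_participant_data",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the generative pipeline.

    rho is a percentage in [0, 100] scaling all four truncated-normal
    parameters of the mu draw; sigma is the Curie-Weiss average
    interaction; density the group-graph edge probability.
    """

    P: int = 40
    N: int = 50
    T: int = 500
    rho: float = 30.0
    sigma: float = 0.1
    density: float = 0.16
    mu_pos_loc: float = 2.73
    mu_pos_scale: float = 2.33
    mu_neg_loc: float = 3.16
    mu_neg_scale: float = 3.35
    gwishart_df: float = 3.0
    seed: int = 0
    mixture: bool = False
    flip_fraction: float = 0.2
    mixture_sizes: tuple[int, int] = (80, 20)

    def __post_init__(self):
        if not (0.0 <= self.rho <= 100.0):
            raise ValueError("rho must be in [0, 100]")
        if not (0.0 < self.density < 1.0):
            raise ValueError("density must be in (0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name in ("mu_pos_scale", "mu_neg_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mixture and sum(self.mixture_sizes) != self.N:
            raise ValueError("mixture_sizes must sum to N")


@dataclass
class SimulationTruth:
    """Everything the simulator knows: the ground truth of one study."""

    space: EdgeSpace
    group_graph: np.ndarray  # (E,) uint8
    mu: np.ndarray  # (E,)
    sigma: float
    individual_graphs: np.ndarray  # (N, E) uint8
    precisions: list[np.ndarray]
    timeseries: list[np.ndarray]
    labels: np.ndarray | None = None  # mixture subgroup per participant
    group_graph_2: np.ndarray | None = None
    config: SimulationConfig | None = None


def simulate_group_graph(
    P: int, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Erdos-Renyi group graph on the edge set: each edge i.i.d. Bernoulli(density)."""
    if not (0.0 <= density < 1.0):
        raise ValueError("density must be in [0, 1)")
    space = EdgeSpace(P)
    return (rng.random(space.E) < density).astype(np.uint8)


def simulate_mu(
    group_graph: np.ndarray,
    rho: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-edge main effects given the group graph.

    Group-present edges get mu_e ~ N(+loc_pos * r, (scale_pos * r)^2)
    truncated to (0, inf); group-absent edges the mirrored negative draw;
    r = rho / 100.  At rho = 0 the vector is exactly zero, making all
    participants independent with edge probability 1/2.
    """
    g = np.asarray(group_graph)
    r = rho / 100.0
    if r == 0.0:
        return np.zeros(g.shape[0])
    mu = np.empty(g.shape[0])
    present = g == 1
    n_pos = int(present.sum())
    loc_p, sc_p = config.mu_pos_loc * r, config.mu_pos_scale * r
    loc_n, sc_n = -config.mu_neg_loc * r, config.mu_neg_scale * r
    if n_pos:
        a = (0.0 - loc_p) / sc_p
        mu[present] = stats.truncnorm.rvs(
            a, np.inf, loc=loc_p, scale=sc_p, size=n_pos, random_state=rng
        )
    n_neg = g.shape[0] - n_pos
    if n_neg:
        b = (0.0 - loc_n) / sc_n
        mu[~present] = stats.truncnorm.rvs(
            -np.inf, b, loc=loc_n, scale=sc_n, size=n_neg, random_state=rng
        )
    return mu


def flip_edges(
    graph: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Invert a round(fraction * E) subset of edges; returns (new_graph, flipped_ids).

    Flipping the same subset again restores the original graph.
    """
    g = np.asarray(graph, dtype=np.uint8).copy()
    n_flip = int(round(fraction * g.shape[0]))
    flipped = rng.choice(g.shape[0], size=n_flip, replace=False)
    g[flipped] ^= 1
    return g, flipped


def _max_det_completion(
    Sigma: np.ndarray,
    adj: np.ndarray,
    tol: float = 1e-9,
    max_cycles: int = 1000,
) -> np.ndarray:
    """Maximum-determinant completion of Sigma over non-edge entries.

    Cyclic per-node updates: for node j with neighbor set B, the column
    W[-j, j] is replaced by W[-j, B] @ W[B, B]^{-1} Sigma[B, j], which
    enforces (W^{-1})_ij = 0 at non-neighbors while keeping W equal to
    Sigma on edges and the diagonal.  Iterates until the max absolute
    change falls below ``tol``.
    """
    P = Sigma.shape[0]
    W = Sigma.copy()
    arange = np.arange(P)
    neighbors = [np.flatnonzero(adj[j]) for j in range(P)]
    for _ in range(max_cycles):
        delta = 0.0
        for j in range(P):
            idx = np.delete(arange, j)
            B = neighbors[j]
            if B.size == 0:
                new_col = np.zeros(P - 1)
            else:
                beta = np.linalg.solve(W[np.ix_(B, B)], Sigma[B, j])
                new_col = W[np.ix_(idx, B)] @ beta
            delta = max(delta, np.abs(new_col - W[idx, j]).max(initial=0.0))
            W[idx, j] = new_col
            W[j, idx] = new_col
        if delta < tol:
            return W
    raise RuntimeError(
        f"completion did not converge in {max_cycles} cycles "
        f"(P={P}, |E|={int(adj.sum() // 2)}, last delta={delta:.3e})"
    )


def sample_gwishart(
    graph: np.ndarray,
    space: EdgeSpace,
    df: float,
    rng: np.random.Generator,
    scale: np.ndarray | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """One exact G-Wishart draw: a PD precision matrix supported on ``graph``.

    Direct scheme: draw an unconstrained Wishart precision (delta = df in
    the G-Wishart convention, i.e. df + P - 1 standard degrees of
    freedom), invert it, replace the implied covariance by its
    maximum-determinant completion over non-edges, and invert back.  The
    non-edge entries of the result are forced to exact zeros (they are
    ~tol already) and positive definiteness is verified.
    """
    if df <= 2:
        raise ValueError("df must exceed 2")
    P = space.P
    scale = np.eye(P) if scale is None else np.asarray(scale, dtype=float)
    g = np.asarray(graph, dtype=np.uint8)
    adj = np.zeros((P, P), dtype=bool)
    adj[space.rows, space.cols] = g == 1
    adj |= adj.T

    K = stats.wishart.rvs(df=df + P - 1, scale=np.linalg.inv(scale), random_state=rng)
    Sigma = np.linalg.inv(K)
    W = _max_det_completion(Sigma, adj, tol=tol)
    Omega = np.linalg.inv(W)
    Omega = 0.5 * (Omega + Omega.T)
    Omega[(~adj) & ~np.eye(P, dtype=bool)] = 0.0
    try:
        np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(
            f"completed precision not positive definite (P={P}, "
            f"edges={int(g.sum())})"
        ) from err
    return Omega


def simulate_participant_data(
    Omega: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    """T i.i.d. draws from N(0, Omega^{-1}) via Cholesky of the covariance."""
    cov = np.linalg.inv(Omega)
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    return rng.standard_normal((T, Omega.shape[0])) @ L.T


def simulate_study(config: SimulationConfig) -> SimulationTruth:
    """Run the full generative pipeline for one study."""
    rng = np.random.default_rng(config.seed)
    space = EdgeSpace(config.P)
    group = simulate_group_graph(config.P, config.density, rng)
    mu = simulate_mu(group, config.rho, config, rng)

    labels = None
    group2 = None
    if config.mixture:
        group2, flipped = flip_edges(group, config.flip_fraction, rng)
        mu2 = mu.copy()
        if flipped.size:
            sub = simulate_mu(group2[flipped], config.rho, config, rng)
            mu2[flipped] = sub
        n1, n2 = config.mixture_sizes
        g1 = cw_sample(GroupState(mu, config.sigma, space), n1, rng)
        g2 = cw_sample(GroupState(mu2, config.sigma, space), n2, rng)
        graphs = np.vstack([g1, g2])
        labels = np.repeat([0, 1], [n1, n2])
    else:
        graphs = cw_sample(GroupState(mu, config.sigma, space), config.N, rng)

    precisions = [
        sample_gwishart(graphs[n], space, config.gwishart_df, rng)
        for n in range(config.N)
    ]
    series = [
        simulate_participant_data(precisions[n], config.T, rng)
        for n in range(config.N)
    ]
    return SimulationTruth(
        space=space,
        group_graph=group,
        mu=mu,
        sigma=config.sigma,
        individual_graphs=graphs,
        precisions=precisions,
        timeseries=series,
        labels=labels,
        group_graph_2=group2,
        config=config,
    )
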