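"""The multilevel Gibbs sampler and its two baseline estimators.

The joint posterior factorizes as

    p(G, S_1..S_N | data)  ∝  prod_n p(data_n | S_n) p(S_n | G) · p(G),

so one Gibbs cycle alternates (a) for every participant, one
spike-and-slab GGM sweep whose indicator update receives the Curie-Weiss
full-conditional log-odds given the group state and the participant's own
current edges, and (b) one Metropolis-within-Gibbs sweep over the group
parameters (mu, sigma) given all participants' indicator vectors.
Participants are conditionally independent given the group, so step (a)
may run on parallel workers; every participant update draws from a random
stream keyed by (chain, iteration, participant), which makes the result
bitwise identical for any worker count.

Baselines: ``individual`` freezes the group at (mu = 0, sigma = 0), i.e.
prior inclusion probability 1/2 with no pooling; ``aggregate`` averages
the per-participant sample precision matrices and fits one GGM to the
implied scatter, assuming no individual differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .curie_weiss import (
    CWTuning,
    GroupPrior,
    GroupState,
    cw_conditional_logodds_all,
    cw_marginal_probs,
    cw_update_params,
)
from .ggm import ParticipantData, PrecisionState, SpikeSlabHyper, ggm_sweep, partial_correlations
from .netcore import EdgeSpace, PosteriorStore

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "fit_multilevel",
    "fit_individual",
    "fit_aggregate",
    "split_rhat",
    "DiagnosticUnavailableError",
]


class DiagnosticUnavailableError(ValueError):
    """Raised when too few draws are available for a convergence diagnostic."""


@dataclass(frozen=True)
class FitConfig:
    """Everything that determines a fit (the seed fully determines the output)."""

    iterations: int = 2000
    burnin: int = 500
    chains: int = 2
    seed: int = 0
    method: str = "multilevel"
    hyper: SpikeSlabHyper = field(default_factory=SpikeSlabHyper)
    prior: GroupPrior = field(default_factory=GroupPrior)
    standardize: bool = True
    parallel_workers: int = 1
    thin: int = 1
    sigma_init: float = 0.05
    aggregate_t_eff: int | None = None  # override round(mean T) for the aggregate fit

    def __post_init__(self):
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("need 0 <= burnin < iterations")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.method not in ("multilevel", "individual", "aggregate"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior summaries of one fit."""

    store: PosteriorStore
    group_probs: np.ndarray  # (E,)
    individual_probs: np.ndarray  # (N, E)
    pcor_means: np.ndarray  # (N, E)
    mu_mean: np.ndarray | None
    mu_sd: np.ndarray | None
    mu_positive_prob: np.ndarray | None  # posterior P(mu_e > 0), the
    # alternative group-level edge score to the model-implied marginal
    sigma_mean: float | None
    sigma_sd: float | None
    rhat_mu: np.ndarray | None
    rhat_sigma: float | None
    log: dict
    config: FitConfig

    @property
    def n_participants(self) -> int:
        return self.individual_probs.shape[0]


def _participant_rng(seed: int, chain: int, iteration: int, participant: int):
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(chain, iteration, participant))
    )


def _update_one(state, data, hyper, logodds, seed, chain, iteration, participant):
    rng = _participant_rng(seed, chain, iteration, participant)
    ggm_sweep(state, data, hyper, logodds, rng)
    return state


def _run_chains(
    data_list: list[ParticipantData],
    config: FitConfig,
    freeze_group: GroupState | None = None,
    progress=None,
):
    """Run all chains; returns (store, group_prob_draws, acceptance, per-chain mu/sigma)."""
    P = data_list[0].P
    if any(d.P != P for d in data_list):
        raise ValueError("all participants must share the same node count P")
    space = EdgeSpace(P)
    N = len(data_list)
    store = PosteriorStore(N, space)
    group_prob_sum = np.zeros(space.E)
    n_group_draws = 0
    acceptance = []

    workers = max(1, config.parallel_workers)
    pool = (
        Parallel(n_jobs=workers, backend="threading") if workers > 1 else None
    )

    for chain in range(config.chains):
        states = [PrecisionState.initial(space) for _ in range(N)]
        gammas = np.zeros((N, space.E), dtype=np.uint8)
        group = freeze_group or GroupState(
            np.zeros(space.E), config.sigma_init, space
        )
        tuning = CWTuning.init(space.E)
        for it in range(config.iterations):
            if freeze_group is not None and freeze_group.sigma == 0.0:
                logodds_rows = np.broadcast_to(freeze_group.mu, (N, space.E))
            else:
                logodds_rows = cw_conditional_logodds_all(
                    gammas, group.mu, group.sigma
                )
            if pool is not None:
                pool(
                    delayed(_update_one)(
                        states[n], data_list[n], config.hyper,
                        logodds_rows[n], config.seed, chain, it, n + 1,
                    )
                    for n in range(N)
                )
            else:
                for n in range(N):
                    _update_one(
                        states[n], data_list[n], config.hyper,
                        logodds_rows[n], config.seed, chain, it, n + 1,
                    )
            for n in range(N):
                gammas[n] = states[n].gamma

            if freeze_group is None:
                tuning.adapt = it < config.burnin
                if it == config.burnin:
                    tuning.reset_counters()
                group_rng = _participant_rng(config.seed, chain, it, 0)
                group = cw_update_params(
                    gammas, group, config.prior, group_rng, tuning
                )

            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                pcors = np.vstack(
                    [partial_correlations(s.Omega, space) for s in states]
                )
                store.append(
                    gammas, group.mu, group.sigma, pcors, chain=chain
                )
                if freeze_group is None:
                    group_prob_sum += cw_marginal_probs(group)
                    n_group_draws += 1
            if progress is not None and (it + 1) % 100 == 0:
                rates = tuning.acceptance_rates if freeze_group is None else {}
                progress(chain, it + 1, rates)
        acceptance.append(tuning.acceptance_rates if freeze_group is None else None)

    group_probs = group_prob_sum / n_group_draws if n_group_draws else None
    return store, group_probs, acceptance


def _summarize(store: PosteriorStore, config: FitConfig, group_probs, acceptance):
    individual_probs = store.inclusion_probs()
    pcor_means = store.pcor_means()
    mu_all, sigma_all = store.group_draws()
    if mu_all is not None:
        mu_mean, mu_sd = mu_all.mean(axis=0), mu_all.std(axis=0)
        mu_positive_prob = (mu_all > 0).mean(axis=0)
        sigma_mean, sigma_sd = float(np.mean(sigma_all)), float(np.std(sigma_all))
    else:  # pragma: no cover - mu is always recorded
        mu_mean = mu_sd = sigma_mean = sigma_sd = mu_positive_prob = None

    rhat_mu = rhat_sigma = None
    if config.chains >= 1 and mu_all is not None:
        mu_chains = np.stack(
            [store.group_draws(chain=c)[0] for c in range(config.chains)]
        )
        sigma_chains = np.stack(
            [store.group_draws(chain=c)[1] for c in range(config.chains)]
        )
        try:
            rhat_mu = split_rhat(mu_chains)
            rhat_sigma = float(split_rhat(sigma_chains))
        except DiagnosticUnavailableError:
            pass

    return FitResult(
        store=store,
        group_probs=np.asarray(group_probs),
        individual_probs=individual_probs,
        pcor_means=pcor_means,
        mu_mean=mu_mean,
        mu_positive_prob=mu_positive_prob,
        mu_sd=mu_sd,
        sigma_mean=sigma_mean,
        sigma_sd=sigma_sd,
        rhat_mu=rhat_mu,
        rhat_sigma=rhat_sigma,
        log={"seed": config.seed, "acceptance": acceptance, "method": config.method},
        config=config,
    )


def fit_multilevel(
    data_list: list[ParticipantData],
    config: FitConfig,
    freeze_group: GroupState | None = None,
    progress=None,
) -> FitResult:
    """Fit the joint multilevel model.

    The reported group-level inclusion probabilities are the posterior
    mean of the model-implied Curie-Weiss marginals over the retained
    (mu, sigma) draws.  ``freeze_group`` pins the group state (used by the
    individual baseline and by exact-equivalence tests).
    """
    config = replace(config, method="multilevel" if freeze_group is None else config.method)
    store, group_probs, acceptance = _run_chains(
        data_list, config, freeze_group=freeze_group, progress=progress
    )
    if group_probs is None:  # frozen group: no marginal-prob draws
        group_probs = store.inclusion_probs().mean(axis=0)
    return _summarize(store, config, group_probs, acceptance)


def fit_individual(
    data_list: list[ParticipantData], config: FitConfig, progress=None
) -> FitResult:
    """Independent per-participant fits: the group frozen at (mu=0, sigma=0).

    Every edge then has prior inclusion probability 1/2 and nothing is
    pooled.  The reported group probabilities are the across-participant
    mean of the individual inclusion probabilities (used only for the
    group-recovery comparison).
    """
    config = replace(config, method="individual")
    space = EdgeSpace(data_list[0].P)
    frozen = GroupState(np.zeros(space.E), 0.0, space)
    result = fit_multilevel(data_list, config, freeze_group=frozen, progress=progress)
    result.log["method"] = "individual"
    return result


def fit_aggregate(
    data_list: list[ParticipantData], config: FitConfig, progress=None
) -> FitResult:
    """Aggregate baseline: average sample precision matrices, fit one GGM.

    Each participant's sample precision (U_n / T_n)^{-1} is computed (with
    a small ridge if T_n <= P or the inversion fails), the average
    precision is inverted to a surrogate covariance, and a single GGM is
    fitted to the implied scatter with T_eff = round(mean T_n)
    observations.  All participants receive copies of the one network.
    """
    config = replace(config, method="aggregate")
    P = data_list[0].P
    precisions = []
    for i, d in enumerate(data_list):
        if d.T <= 0:
            raise ValueError(f"participant {i + 1} has no observations")
        S = d.U / d.T
        ridge = 1e-3 * np.trace(S) / P
        if d.T <= P:
            S = S + ridge * np.eye(P)
        try:
            precisions.append(np.linalg.inv(S))
        except np.linalg.LinAlgError:
            precisions.append(np.linalg.inv(S + ridge * np.eye(P)))
    P_bar = np.mean(precisions, axis=0)
    try:
        C = np.linalg.inv(P_bar)
        np.linalg.cholesky(0.5 * (C + C.T))
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "averaged precision matrix is singular; a larger ridge is needed"
        ) from err
    C = 0.5 * (C + C.T)
    t_eff = config.aggregate_t_eff or int(round(np.mean([d.T for d in data_list])))
    agg = ParticipantData(U=t_eff * C, T=t_eff)

    space = EdgeSpace(P)
    frozen = GroupState(np.zeros(space.E), 0.0, space)
    result = fit_multilevel([agg], config, freeze_group=frozen, progress=progress)
    one = result.individual_probs[0]
    result.group_probs = one.copy()
    result.individual_probs = np.tile(one, (len(data_list), 1))
    result.pcor_means = np.tile(result.pcor_means[0], (len(data_list), 1))
    result.log["method"] = "aggregate"
    result.log["t_eff"] = t_eff
    return result


def fit(data_list: list[ParticipantData], config: FitConfig, progress=None) -> FitResult:
    """Dispatch on ``config.method``."""
    if config.method == "multilevel":
        return fit_multilevel(data_list, config, progress=progress)
    if config.method == "individual":
        return fit_individual(data_list, config, progress=progress)
    return fit_aggregate(data_list, config, progress=progress)


def split_rhat(chains: np.ndarray):
    """Split-chain potential scale reduction.

    ``chains`` has shape (m, n) or (m, n, k) for k parameters.  Each chain
    is split in half, giving 2m sequences; with W the mean within-sequence
    variance and B/n the variance of the sequence means, the statistic is
    sqrt(((n-1)/n W + B/n) / W) — near 1 at convergence, > 1 when chains
    disagree.  Constant chains (zero variance everywhere) report exactly 1.
    """
    x = np.asarray(chains, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[..., None]
    m, n, k = x.shape
    if n < 4:
        raise DiagnosticUnavailableError(
            f"need at least 4 draws per chain, got {n}"
        )
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    means = halves.mean(axis=1)  # (2m, k)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(var_plus == 0.0, 1.0, rhat)
    rhat = np.where((W == 0.0) & (var_plus > 0.0), np.inf, rhat)
    return float(rhat[0]) if squeeze else rhat
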