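"""Individual-level Gaussian graphical model with a spike-and-slab prior.

One participant's (preprocessed, zero-mean) signal ``x_t`` is modelled as
multivariate normal with precision matrix Omega; a zero off-diagonal
``omega_ij = 0`` means nodes i and j are conditionally independent.  The
prior places an exponential(lambda) on each diagonal element and a
two-component normal mixture on each off-diagonal element:

    omega_ij | gamma_ij ~ N(0, v1^2) if gamma_ij = 1 else N(0, v0^2),

with v0 << v1, so gamma_ij = 0 shrinks the element to (almost) zero — the
edge-indicator vector gamma is the participant's network structure.

Inference is column-wise block Gibbs in the stochastic-search style: each
column of Omega (off-diagonal block plus diagonal) has a conjugate
multivariate-normal / gamma full conditional, and the indicators are
Bernoulli given Omega.  The prior log-odds fed to the indicator update is
where the group-level network enters the multilevel sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit

from .netcore import EdgeSpace

__all__ = [
    "SpikeSlabHyper",
    "ParticipantData",
    "PrecisionState",
    "DegenerateColumnError",
    "prepare_data",
    "ggm_log_likelihood",
    "sample_precision_column",
    "sample_edge_indicators",
    "ggm_sweep",
    "partial_correlations",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateColumnError(ValueError):
    """Raised when a column cannot be standardized (zero sample variance)."""


@dataclass(frozen=True)
class SpikeSlabHyper:
    """Spike/slab standard deviations and diagonal exponential rate.

    ``v0`` and ``v1`` are standard deviations (squared inside the normal
    densities); the defaults give the common 50x spike/slab ratio, which
    is scale-meaningful when the data are standardized.
    """

    v0: float = 0.02
    v1: float = 1.0
    lam: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.v0 < self.v1):
            raise ValueError(f"need 0 < v0 < v1, got v0={self.v0}, v1={self.v1}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lambda must be positive, got {self.lam}")


@dataclass
class ParticipantData:
    """Centered time series and its scatter matrix for one participant.

    ``U = X^T X`` equals ``T`` times the (biased) sample covariance of the
    centered series.  ``X`` may be None when only ``U`` and ``T`` are known
    (e.g. the aggregate baseline, or a prior-only chain with T = 0).
    """

    U: np.ndarray
    T: int
    X: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2 or self.U.shape[0] != self.U.shape[1]:
            raise ValueError("U must be a square matrix")
        if not np.allclose(self.U, self.U.T, atol=1e-10):
            raise ValueError("U must be symmetric")

    @property
    def P(self) -> int:
        return self.U.shape[0]

    @classmethod
    def prior_only(cls, P: int) -> "ParticipantData":
        """A data-free participant (T = 0): the chain samples the prior."""
        return cls(U=np.zeros((P, P)), T=0)


def prepare_data(
    raw: np.ndarray,
    standardize: bool = True,
    labels: list[str] | None = None,
) -> ParticipantData:
    """Center (and optionally standardize) a T x P series, build the scatter.

    Raises :class:`DegenerateColumnError`, naming the node, if a column is
    constant while standardization is requested.
    """
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2:
        raise ValueError("raw data must be a T x P matrix")
    T, P = X.shape
    if T < 2 or P < 2:
        raise ValueError(f"need T >= 2 and P >= 2, got T={T}, P={P}")
    if not np.isfinite(X).all():
        raise ValueError("raw data contains non-finite entries")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            name = labels[bad[0]] if labels else f"column {bad[0] + 1}"
            raise DegenerateColumnError(
                f"cannot standardize constant node {name}"
            )
        X = X / sd
    return ParticipantData(U=X.T @ X, T=T, X=X, labels=labels)


def ggm_log_likelihood(data: ParticipantData, Omega: np.ndarray) -> float:
    """Gaussian log-likelihood -(TP/2) log 2pi + (T/2) log|Omega| - tr(Omega U)/2."""
    Omega = np.asarray(Omega, dtype=float)
    try:
        L = np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError as err:
        raise ValueError("Omega is not positive definite") from err
    logdet = 2.0 * np.log(np.diag(L)).sum()
    T, P = data.T, data.P
    return float(
        -0.5 * T * P * _LOG_2PI + 0.5 * T * logdet - 0.5 * np.trace(Omega @ data.U)
    )


@dataclass
class PrecisionState:
    """Current precision matrix and edge indicators for one participant."""

    Omega: np.ndarray
    gamma: np.ndarray
    space: EdgeSpace

    def __post_init__(self):
        self.Omega = np.asarray(self.Omega, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=np.uint8)
        if self.Omega.shape != (self.space.P, self.space.P):
            raise ValueError("Omega shape does not match the edge space")
        if self.gamma.shape != (self.space.E,):
            raise ValueError("gamma length does not match the edge space")

    @classmethod
    def initial(cls, space: EdgeSpace) -> "PrecisionState":
        """Neutral start: identity precision, empty graph."""
        return cls(Omega=np.eye(space.P), gamma=np.zeros(space.E, np.uint8), space=space)


def sample_precision_column(
    state: PrecisionState,
    data: ParticipantData,
    hyper: SpikeSlabHyper,
    j: int,
    rng: np.random.Generator,
) -> PrecisionState:
    """Block-Gibbs update of column/row ``j`` (0-based) of Omega in place.

    With ``idx`` the other nodes, the off-diagonal block has the conjugate
    conditional  u ~ N(-C U[idx, j], C),
    C = [(U_jj + lambda) Omega[idx, idx]^{-1} + D^{-1}]^{-1}, where D holds
    the squared spike/slab sds of the incident edges; the diagonal is
    omega_jj = g + u' Omega[idx, idx]^{-1} u with
    g ~ Gamma(1 + T/2, rate (U_jj + lambda)/2).  The Schur complement g > 0
    keeps Omega positive definite by construction.
    """
    P = state.space.P
    if not (0 <= j < P):
        raise ValueError(f"column id {j} out of range [0, {P})")
    U = data.U
    Omega = state.Omega
    idx = np.delete(np.arange(P), j)
    O11 = Omega[np.ix_(idx, idx)]
    try:
        L11 = np.linalg.cholesky(O11)
    except np.linalg.LinAlgError as err:
        raise FloatingPointError(
            f"submatrix for column {j + 1} lost positive definiteness"
        ) from err

    ujj = U[j, j]
    eids = state.space.incident_edge_ids(j)
    v = np.where(state.gamma[eids] == 1, hyper.v1, hyper.v0)

    inv11 = cho_solve((L11, True), np.eye(P - 1), check_finite=False)
    M = (ujj + hyper.lam) * inv11
    M[np.diag_indices(P - 1)] += 1.0 / v**2
    try:
        Lm = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as err:
        raise FloatingPointError(
            f"conditional covariance for column {j + 1} not positive definite"
        ) from err
    mean = -cho_solve((Lm, True), U[idx, j], check_finite=False)
    z = rng.standard_normal(P - 1)
    u = mean + solve_triangular(Lm.T, z, lower=False, check_finite=False)

    g = rng.gamma(1.0 + 0.5 * data.T, 2.0 / (ujj + hyper.lam))
    w = inv11 @ u
    Omega[idx, j] = u
    Omega[j, idx] = u
    Omega[j, j] = g + u @ w
    return state


def sample_edge_indicators(
    state: PrecisionState,
    hyper: SpikeSlabHyper,
    prior_logodds: np.ndarray,
    rng: np.random.Generator,
) -> PrecisionState:
    """Draw all edge indicators given the current precision matrix.

    Each gamma_e is Bernoulli with log-odds equal to the slab/spike density
    ratio at the current off-diagonal element plus the supplied prior
    log-odds (the group-level conditional in the multilevel sampler, zero
    for an individual-only fit).  Log-odds are clipped at +-700 before
    exponentiation.
    """
    prior_logodds = np.asarray(prior_logodds, dtype=float)
    if prior_logodds.shape != (state.space.E,):
        raise ValueError("prior_logodds length does not match the edge space")
    omega = state.Omega[state.space.rows, state.space.cols]
    # log N(w; 0, v1^2) - log N(w; 0, v0^2)
    logodds = (
        np.log(hyper.v0 / hyper.v1)
        + 0.5 * omega**2 * (1.0 / hyper.v0**2 - 1.0 / hyper.v1**2)
        + prior_logodds
    )
    p = expit(np.clip(logodds, -700.0, 700.0))
    state.gamma = (rng.random(state.space.E) < p).astype(np.uint8)
    return state


def ggm_sweep(
    state: PrecisionState,
    data: ParticipantData,
    hyper: SpikeSlabHyper,
    prior_logodds: np.ndarray,
    rng: np.random.Generator,
) -> PrecisionState:
    """One full Gibbs pass: indicators first, then columns 1..P in order."""
    sample_edge_indicators(state, hyper, prior_logodds, rng)
    for j in range(state.space.P):
        sample_precision_column(state, data, hyper, j, rng)
    return state


def partial_correlations(Omega: np.ndarray, space: EdgeSpace) -> np.ndarray:
    """Edge-ordered partial correlations r_e = -omega_ij / sqrt(omega_ii omega_jj)."""
    d = np.sqrt(np.diag(Omega))
    return -Omega[space.rows, space.cols] / (d[space.rows] * d[space.cols])
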