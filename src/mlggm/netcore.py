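"""Edge-space indexing, bit-packed posterior storage, and posterior summaries.

Every network in this package lives on the edge set of an undirected graph
over ``P`` nodes.  Edges are enumerated lexicographically over node pairs
``(i, j)`` with ``i < j`` — the order produced by ``numpy.triu_indices`` —
which gives ``E = P(P-1)/2`` edges.  Node and edge identifiers are 1-based
in every file the package writes and 0-based internally.

Binary edge-indicator draws from the Gibbs sampler are retained with one
bit per (participant, edge, iteration) triple, so storing the full
posterior over network structures stays cheap even for hundreds of
participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EdgeSpace",
    "EdgeVector",
    "PosteriorStore",
    "InvalidEdgeError",
    "EmptyStoreError",
    "edge_index",
    "edge_pair",
    "pack_edges",
    "unpack_edges",
    "posterior_summary",
    "edge_table",
]


class InvalidEdgeError(ValueError):
    """Raised for node pairs that do not define a valid (i < j) edge."""


class EmptyStoreError(ValueError):
    """Raised when posterior summaries are requested from a store with no draws."""


class EdgeSpace:
    """The set of ``E = P(P-1)/2`` undirected edges over ``P`` nodes.

    Provides the bijection between edge ids and node pairs, plus the
    incidence lookups the precision-matrix sampler needs.
    """

    __slots__ = ("P", "_rows", "_cols", "_edge_matrix")

    def __init__(self, P: int):
        P = int(P)
        if P < 2:
            raise ValueError(f"need at least 2 nodes, got P={P}")
        self.P = P
        rows, cols = np.triu_indices(P, 1)
        self._rows = rows
        self._cols = cols
        mat = np.full((P, P), -1, dtype=np.int64)
        mat[rows, cols] = np.arange(rows.size)
        mat[cols, rows] = mat[rows, cols]
        self._edge_matrix = mat

    @property
    def E(self) -> int:
        return self.P * (self.P - 1) // 2

    @property
    def rows(self) -> np.ndarray:
        """0-based first node of each edge, in edge order."""
        return self._rows

    @property
    def cols(self) -> np.ndarray:
        """0-based second node of each edge, in edge order."""
        return self._cols

    def incident_edge_ids(self, j: int) -> np.ndarray:
        """0-based edge ids for pairs ``(i, j)``, ``i != j``, ordered by i.

        The order matches ``numpy.delete(arange(P), j)``, i.e. the row
        order of the submatrix with node ``j`` removed.
        """
        idx = np.delete(np.arange(self.P), j)
        return self._edge_matrix[idx, j]

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeSpace) and other.P == self.P

    def __hash__(self) -> int:
        return hash(("EdgeSpace", self.P))

    def __repr__(self) -> str:
        return f"EdgeSpace(P={self.P}, E={self.E})"


def edge_index(i: int, j: int, space: EdgeSpace) -> int:
    """Map a 1-based node pair ``(i, j)``, ``i < j``, to its 1-based edge id."""
    if not (1 <= i < j <= space.P):
        raise InvalidEdgeError(
            f"({i}, {j}) is not a valid edge for P={space.P}; need 1 <= i < j <= P"
        )
    return int(space._edge_matrix[i - 1, j - 1]) + 1


def edge_pair(e: int, space: EdgeSpace) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: 1-based edge id to 1-based ``(i, j)``."""
    if not (1 <= e <= space.E):
        raise InvalidEdgeError(f"edge id {e} out of range [1, {space.E}]")
    return int(space._rows[e - 1]) + 1, int(space._cols[e - 1]) + 1


def _as_edge_values(gamma, space: EdgeSpace | None = None) -> np.ndarray:
    """Coerce an EdgeVector or array-like to a validated uint8 array."""
    if isinstance(gamma, EdgeVector):
        if space is not None and gamma.space != space:
            raise ValueError("EdgeVector space does not match")
        return gamma.values
    values = np.asarray(gamma)
    if space is not None and values.shape[-1] != space.E:
        raise ValueError(f"expected {space.E} edge entries, got {values.shape[-1]}")
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError("edge indicators must be 0 or 1")
    return values.astype(np.uint8)


@dataclass
class EdgeVector:
    """A binary indicator over all edges of an :class:`EdgeSpace`.

    The per-participant network structure: entry ``e`` is 1 when edge ``e``
    is present in the graph.
    """

    values: np.ndarray
    space: EdgeSpace

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 1 or values.shape[0] != self.space.E:
            raise ValueError(
                f"expected {self.space.E} entries for P={self.space.P}, "
                f"got shape {values.shape}"
            )
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("edge indicators must be 0 or 1")
        self.values = values.astype(np.uint8)

    @property
    def count(self) -> int:
        """Number of present edges, s = sum_e gamma_e."""
        return int(self.values.sum())

    def to_adjacency(self) -> np.ndarray:
        adj = np.zeros((self.space.P, self.space.P), dtype=np.uint8)
        adj[self.space.rows, self.space.cols] = self.values
        adj[self.space.cols, self.space.rows] = self.values
        return adj


def pack_edges(values: np.ndarray) -> np.ndarray:
    """Bit-pack a binary vector (or row-wise a binary matrix)."""
    arr = np.asarray(values, dtype=np.uint8)
    return np.packbits(arr, axis=-1)


def unpack_edges(packed: np.ndarray, E: int) -> np.ndarray:
    """Invert :func:`pack_edges`, recovering the first ``E`` bits per row."""
    return np.unpackbits(np.asarray(packed, dtype=np.uint8), axis=-1, count=E)


class PosteriorStore:
    """Bit-packed storage of retained MCMC draws.

    Keeps every retained edge-indicator draw (1 bit per participant x edge
    x iteration) together with running inclusion counts, running
    partial-correlation sums, and the per-iteration group-level parameter
    draws (mu vector and sigma).
    """

    def __init__(self, n_participants: int, space: EdgeSpace):
        if n_participants < 1:
            raise ValueError("need at least one participant")
        self.space = space
        self.n_participants = int(n_participants)
        self._packed: list[np.ndarray] = []
        self._mu: list[np.ndarray] = []
        self._sigma: list[float] = []
        self._chain: list[int] = []
        self._incl = np.zeros((n_participants, space.E))
        self._pcor = np.zeros((n_participants, space.E))

    @property
    def n_iterations(self) -> int:
        return len(self._packed)

    @property
    def packed_nbytes(self) -> int:
        return sum(arr.nbytes for arr in self._packed)

    def append(
        self,
        gammas: np.ndarray,
        mu: np.ndarray | None = None,
        sigma: float | None = None,
        pcors: np.ndarray | None = None,
        chain: int = 0,
    ) -> None:
        """Record one retained iteration.

        ``gammas`` is the (n_participants, E) binary indicator matrix;
        ``pcors`` the matching partial-correlation matrix for the running
        means; ``mu``/``sigma`` the group-level draw.
        """
        gammas = np.asarray(gammas, dtype=np.uint8)
        if gammas.shape != (self.n_participants, self.space.E):
            raise ValueError(
                f"expected shape {(self.n_participants, self.space.E)}, "
                f"got {gammas.shape}"
            )
        self._packed.append(np.packbits(gammas, axis=1))
        self._incl += gammas
        if pcors is not None:
            self._pcor += np.asarray(pcors)
        if mu is not None:
            self._mu.append(np.asarray(mu, dtype=float).copy())
        self._sigma.append(float(sigma) if sigma is not None else np.nan)
        self._chain.append(int(chain))

    def draw(self, iteration: int) -> np.ndarray:
        """Unpack the indicator draws of one retained iteration, (N, E)."""
        return unpack_edges(self._packed[iteration], self.space.E)

    def inclusion_probs(self) -> np.ndarray:
        """Per-(participant, edge) posterior inclusion probability, (N, E)."""
        if self.n_iterations == 0:
            raise EmptyStoreError("no retained draws")
        return self._incl / self.n_iterations

    def pcor_means(self) -> np.ndarray:
        if self.n_iterations == 0:
            raise EmptyStoreError("no retained draws")
        return self._pcor / self.n_iterations

    def group_draws(self, chain: int | None = None):
        """Retained group-level draws as ``(mu, sigma)`` arrays.

        ``mu`` has shape (n_draws, E) (or None when the group level was
        frozen) and ``sigma`` shape (n_draws,).  Pass ``chain`` to select
        the draws of a single chain.
        """
        sigma = np.asarray(self._sigma)
        mu = np.vstack(self._mu) if self._mu else None
        if chain is not None:
            mask = np.asarray(self._chain) == chain
            sigma = sigma[mask]
            mu = mu[mask] if mu is not None else None
        return mu, sigma

    @property
    def chain_ids(self) -> np.ndarray:
        return np.asarray(self._chain)


def posterior_summary(store: PosteriorStore) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities and their standard deviations.

    Because the retained draws are Bernoulli, the posterior standard
    deviation of the indicator is ``sqrt(p (1 - p))``, bounded by 0.5.
    Returns ``(probs, sds)``, each of shape (n_participants, E).
    """
    probs = store.inclusion_probs()
    sds = np.sqrt(probs * (1.0 - probs))
    return probs, sds


def edge_table(space: EdgeSpace) -> pd.DataFrame:
    """The canonical edge table: 1-based ``node_i``, ``node_j``, ``edge_id``."""
    return pd.DataFrame(
        {
            "node_i": space.rows + 1,
            "node_j": space.cols + 1,
            "edge_id": np.arange(space.E) + 1,
        }
    )
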