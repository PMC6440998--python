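"""Continuous-time Markov kinetic models of conformational exchange.

A :class:`KineticModel` bundles the quantities that define a K-state
conformational process observed through FRET: one efficiency per state,
a conservative rate matrix ``Q`` (s^-1), its stationary distribution and
a connectivity mask restricting which transitions are allowed.  The
default connectivity for multi-state models is a sequential chain
(1<->2<->3, no direct 1<->3 exchange), which is how the ClpB M domain
interconverts between its active, inactive and minor states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "KineticModel",
    "sequential_connectivity",
    "stationary_distribution",
    "wt_mdomain_model",
]


def sequential_connectivity(K: int) -> np.ndarray:
    """Boolean mask allowing only nearest-neighbour transitions i <-> i+1."""
    mask = np.zeros((K, K), dtype=bool)
    for i in range(K - 1):
        mask[i, i + 1] = mask[i + 1, i] = True
    return mask


def _validate_rate_matrix(Q: np.ndarray, atol: float = 1e-8) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -atol):
        raise ValueError("rate matrix has negative off-diagonal entries")
    rows = Q.sum(axis=1)
    if np.any(np.abs(rows) > atol * max(1.0, np.abs(Q).max())):
        raise ValueError(
            f"rate matrix rows must sum to zero (non-conservative; row sums {rows})"
        )


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Unique pi with pi @ Q = 0 and sum(pi) = 1.

    Raises
    ------
    ValueError
        If ``Q`` is not a valid conservative rate matrix, or the chain is
        reducible on its allowed graph (no unique stationary distribution).
    """
    Q = np.asarray(Q, dtype=float)
    _validate_rate_matrix(Q)
    if Q.shape[0] == 1:
        return np.ones(1)
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components((Q > 0).astype(int), directed=True,
                                              connection="strong")
        groups = [list(np.flatnonzero(labels == c) + 1) for c in range(n_comp)]
        raise ValueError(
            f"rate matrix is reducible; disconnected state groups: {groups}"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("chain appears reducible: stationary vector not positive")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass
class KineticModel:
    """K FRET states exchanging as a continuous-time Markov chain.

    Parameters
    ----------
    E : array of shape (K,)
        Apparent (raw-scale) FRET efficiency of each state.
    Q : array of shape (K, K)
        Rate matrix in s^-1; off-diagonals >= 0, rows sum to zero.
    connectivity : bool array of shape (K, K), optional
        Allowed transitions.  Defaults to the support of ``Q`` off the
        diagonal.  Masked entries of ``Q`` must be exactly zero.
    """

    E: np.ndarray
    Q: np.ndarray
    connectivity: np.ndarray | None = None
    pi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.E = np.atleast_1d(np.asarray(self.E, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.E.shape[0] != self.Q.shape[0]:
            raise ValueError("E and Q disagree on the number of states")
        if np.any((self.E < 0) | (self.E > 1)):
            raise ValueError("state efficiencies must lie in [0, 1]")
        _validate_rate_matrix(self.Q)
        if self.connectivity is None:
            self.connectivity = (self.Q > 0) & ~np.eye(self.K, dtype=bool)
        else:
            self.connectivity = np.asarray(self.connectivity, dtype=bool)
            off = self.Q - np.diag(np.diag(self.Q))
            if np.any((off != 0) & ~self.connectivity):
                raise ValueError("rate matrix has nonzero entries outside connectivity")
        self.pi = stationary_distribution(self.Q) if self.K > 1 else np.ones(1)

    @property
    def K(self) -> int:
        return self.E.shape[0]

    def rate(self, i: int, j: int) -> float:
        """Transition rate k_ij (1-based state labels, as in the field)."""
        return float(self.Q[i - 1, j - 1])

    def canonical(self) -> "KineticModel":
        """Return the model with states reordered by descending efficiency.

        For chain connectivity only the identity or full reversal keep the
        chain structure, so the chain is reversed when its efficiencies run
        uphill; otherwise states are sorted by descending E.
        """
        K = self.K
        chain = np.array_equal(self.connectivity, sequential_connectivity(K))
        if chain and K > 1:
            order = np.arange(K)[::-1] if self.E[0] < self.E[-1] else np.arange(K)
        else:
            order = np.argsort(-self.E, kind="stable")
        return KineticModel(
            E=self.E[order],
            Q=self.Q[np.ix_(order, order)],
            connectivity=self.connectivity[np.ix_(order, order)],
        )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "E": self.E.tolist(),
            "Q": self.Q.tolist(),
            "pi": self.pi.tolist(),
            "connectivity": self.connectivity.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            E=np.asarray(d["E"], dtype=float),
            Q=np.asarray(d["Q"], dtype=float),
            connectivity=np.asarray(d["connectivity"], dtype=bool),
        )

    @classmethod
    def from_rates(cls, E, rates: dict[tuple[int, int], float]) -> "KineticModel":
        """Build a model from 1-based rates, e.g. ``{(1, 2): 5300, ...}``."""
        E = np.atleast_1d(np.asarray(E, dtype=float))
        K = E.shape[0]
        Q = np.zeros((K, K))
        for (i, j), k in rates.items():
            if i == j:
                raise ValueError("diagonal rates are not free parameters")
            Q[i - 1, j - 1] = k
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(E=E, Q=Q)


def wt_mdomain_model() -> KineticModel:
    """Three-state sequential model of wild-type ClpB M-domain dynamics.

    State 1 (active, high FRET), state 2 (inactive), state 3 (minor), with
    microsecond-scale 1<->2 exchange and slower 2<->3 exchange.  Used as the
    default preset for simulations and recovery tests.
    """
    return KineticModel.from_rates(
        E=[0.8, 0.47, 0.15],
        rates={(1, 2): 5300.0, (2, 1): 5700.0, (2, 3): 800.0, (3, 2): 2300.0},
    )
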