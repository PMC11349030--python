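"""Synthetic multi-group DAG families and non-Gaussian observations.

A family of K related ground-truth DAGs is built by sampling a random DAG,
weighting its edges, and then repeatedly applying a small random
edge-turnover (remove a fraction of edges, add the same number elsewhere)
so that consecutive groups share most of their structure.  Observations are
drawn from the linear structural equation model ``X = B^T X + eps`` with
independent centered chi-squared(1) errors, which are strongly skewed and
hence non-Gaussian — the identification signal for LiNGAM-type estimators.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "GroundTruthSet",
    "sample_random_dag",
    "assign_weights",
    "perturb_dag",
    "generate_data",
    "generate_study",
    "topological_order",
    "is_acyclic",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a K-group simulated family.

    ``d`` is the mean edge degree: every admissible node pair carries an
    edge independently with probability ``d / (p - 1)``, so the expected
    number of edges is ``p * d / 2``.
    """

    K: int = 3
    p: int = 200
    N: int = 750
    d: float = 2.0
    perturb_frac: float = 0.05
    weight_low: float = 0.3
    weight_high: float = 0.8
    add_low: float = 0.3
    add_high: float = 0.5
    noise_spec: str = "chisq1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.N % self.K != 0:
            raise ValueError("N must be divisible by K (equal group sizes)")
        if not 0.0 <= self.perturb_frac < 1.0:
            raise ValueError("perturb_frac must lie in [0, 1)")
        if not 0.0 < self.weight_low < self.weight_high:
            raise ValueError("need 0 < weight_low < weight_high")

    @property
    def n_per_group(self) -> int:
        return self.N // self.K


@dataclass
class GroundTruthSet:
    """The K true weighted adjacency matrices and a topological order each."""

    B_list: list[np.ndarray] = field(default_factory=list)
    order_list: list[np.ndarray] = field(default_factory=list)


def topological_order(B: np.ndarray) -> np.ndarray:
    """Topological order of the DAG with weight matrix ``B`` (edge i->j iff
    B[i, j] != 0).  Raises ``ValueError`` if the graph has a cycle.

    Kahn's algorithm with smallest-index-first tie-breaking, so the result
    is deterministic.
    """
    B = np.asarray(B)
    p = B.shape[0]
    if B.shape != (p, p):
        raise ValueError("adjacency must be square")
    adj = B != 0
    indeg = adj.sum(axis=0).astype(int)
    order: list[int] = []
    avail = sorted(np.flatnonzero(indeg == 0).tolist())
    while avail:
        i = avail.pop(0)
        order.append(i)
        for j in np.flatnonzero(adj[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                bisect.insort(avail, int(j))
        adj[i, :] = False
    if len(order) != p:
        raise ValueError("graph contains a directed cycle")
    return np.asarray(order, dtype=int)


def is_acyclic(B: np.ndarray) -> bool:
    try:
        topological_order(B)
        return True
    except ValueError:
        return False


def sample_random_dag(p: int, d: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a binary DAG adjacency on ``p`` nodes with mean degree ``d``.

    A uniformly random node permutation fixes a causal order; each of the
    ``p(p-1)/2`` pairs admissible under that order carries an edge
    independently with probability ``d / (p - 1)``.  The permutation step
    ensures the variable index does not encode the causal order.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0.0 < d <= p - 1:
        raise ValueError(f"mean degree d must lie in (0, p-1]; got {d}")
    prob = d / (p - 1)
    perm = rng.permutation(p)  # perm[rank] = node at that causal position
    lower = np.tril(rng.random((p, p)) < prob, k=-1)  # rank-space edges r2 -> r1? no: row>col
    adj = np.zeros((p, p), dtype=bool)
    rows, cols = np.nonzero(lower)
    # lower[r, s] with r > s means edge from earlier rank s to later rank r
    adj[perm[cols], perm[rows]] = True
    return adj.astype(np.int8)


def assign_weights(
    adj: np.ndarray,
    rng: np.random.Generator,
    low: float = 0.3,
    high: float = 0.8,
) -> np.ndarray:
    """Weight each edge from Unif(-high, -low) ∪ (low, high), equal mass per branch."""
    adj = np.asarray(adj)
    if not is_acyclic(adj):
        raise ValueError("input adjacency is cyclic")
    B = np.zeros(adj.shape, dtype=float)
    idx = np.nonzero(adj)
    m = idx[0].size
    mag = rng.uniform(low, high, size=m)
    sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
    B[idx] = sign * mag
    return B


def perturb_dag(
    B_prev: np.ndarray,
    frac: float,
    rng: np.random.Generator,
    add_low: float = 0.3,
    add_high: float = 0.5,
) -> np.ndarray:
    """Edge turnover: remove ``floor(frac * |E|)`` random edges and add the
    same number at random empty positions, keeping the result acyclic.

    New positions are drawn only among pairs consistent with a fixed
    topological order of ``B_prev`` (acyclicity by construction) and
    exclude the positions removed in this same call, so the stated
    turnover is real.  Added weights are Unif[add_low, add_high].
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must lie in [0, 1)")
    B = np.array(B_prev, dtype=float, copy=True)
    order = topological_order(B)  # raises on cyclic input
    if frac == 0.0:
        return B
    edges = np.argwhere(B != 0)
    m = edges.shape[0]
    k = int(np.floor(frac * m))
    if k == 0:
        return B
    rm = edges[rng.choice(m, size=k, replace=False)]
    removed = {(int(i), int(j)) for i, j in rm}
    B[rm[:, 0], rm[:, 1]] = 0.0

    pos_of = np.empty(len(order), dtype=int)
    pos_of[order] = np.arange(len(order))
    p = B.shape[0]
    ii, jj = np.nonzero(np.ones((p, p), dtype=bool) & ~np.eye(p, dtype=bool))
    admissible = [
        (int(i), int(j))
        for i, j in zip(ii, jj)
        if pos_of[i] < pos_of[j] and B[i, j] == 0 and (int(i), int(j)) not in removed
    ]
    if len(admissible) < k:
        raise RuntimeError(
            f"cannot add {k} edges: only {len(admissible)} admissible empty positions"
        )
    pick = rng.choice(len(admissible), size=k, replace=False)
    w = rng.uniform(add_low, add_high, size=k)
    for t, a in enumerate(pick):
        i, j = admissible[a]
        B[i, j] = w[t]
    return B


def generate_data(
    B: np.ndarray,
    n: int,
    rng: np.random.Generator,
    noise_spec: str = "chisq1",
) -> np.ndarray:
    """Draw ``n`` i.i.d. rows of X solving ``X = B^T X + eps``.

    eps_i are i.i.d. chi-squared(1) minus 1 (mean 0, variance 2) unless
    ``noise_spec`` selects another law.  Solved exactly via the linear
    system ``(I - B^T) x = eps``; for an acyclic B this system is always
    non-singular.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if not is_acyclic(B):
        raise ValueError("B must be acyclic")
    if noise_spec == "chisq1":
        E = rng.chisquare(1, size=(n, p)) - 1.0
    elif noise_spec == "uniform":
        E = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(n, p))
    else:
        raise ValueError(f"unknown noise_spec {noise_spec!r}")
    A = np.eye(p) - B.T
    # rows x satisfy A x = eps  =>  X = solve(A, E^T)^T
    X = np.linalg.solve(A, E.T).T
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite values solving (I - B^T) x = eps")
    return X


def generate_study(config: SimulationConfig) -> tuple[GroundTruthSet, list[np.ndarray]]:
    """Generate the full K-group study: B^1 fresh, B^k a perturbation of
    B^{k-1}, and n = N/K observation rows per group.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruthSet()
    adj = sample_random_dag(config.p, config.d, rng)
    B = assign_weights(adj, rng, config.weight_low, config.weight_high)
    truth.B_list.append(B)
    truth.order_list.append(topological_order(B))
    for _ in range(1, config.K):
        B = perturb_dag(
            truth.B_list[-1], config.perturb_frac, rng, config.add_low, config.add_high
        )
        truth.B_list.append(B)
        truth.order_list.append(topological_order(B))
    n = config.n_per_group
    X_list = [
        generate_data(Bk, n, rng, noise_spec=config.noise_spec) for Bk in truth.B_list
    ]
    return truth, X_list
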