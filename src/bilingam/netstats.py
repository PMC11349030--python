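"""Evaluation metrics and directed-network analysis.

Benchmarking metrics over directed edges (confusion counts, TPR, FDR,
structural Hamming distance, Jaccard similarity) and the analysis layer
applied to estimated networks: degree-based hub detection, module-wise
edge-flow counts with hypergeometric enrichment tests, common/distinctive
pattern extraction across groups, and subsampling robustness summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "HubReport",
    "confusion_counts",
    "tpr_fdr",
    "shd",
    "jaccard",
    "edge_set",
    "detect_hubs",
    "module_flow_counts",
    "hypergeometric_enrichment",
    "common_distinct_patterns",
    "robustness_subsample",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Directed-edge confusion counts over all ordered node pairs."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _binary(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("adjacency must be square")
    A = (B != 0).astype(bool)
    np.fill_diagonal(A, False)
    return A


def confusion_counts(B_true: np.ndarray, B_est: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN of directed-edge presence over the p(p-1) ordered pairs."""
    T = _binary(B_true)
    E = _binary(B_est)
    if T.shape != E.shape:
        raise ValueError("dimension mismatch between true and estimated graphs")
    off = ~np.eye(T.shape[0], dtype=bool)
    tp = int(np.sum(T & E))
    fp = int(np.sum(~T & E))
    fn = int(np.sum(T & ~E))
    tn = int(np.sum(~T & ~E & off))
    return ConfusionCounts(tp, fp, fn, tn)


def tpr_fdr(c: ConfusionCounts) -> tuple[float, float]:
    """TPR = TP/(TP+FN); FDR = FP/(FP+TP).

    With no actual positives TPR is undefined and returned as NaN; with no
    predicted edges FDR is returned as 0 (no discovery, no false discovery).
    """
    tpr = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else float("nan")
    fdr = c.FP / (c.FP + c.TP) if (c.FP + c.TP) > 0 else 0.0
    return tpr, fdr


def shd(B_true: np.ndarray, B_est: np.ndarray) -> int:
    """Structural Hamming distance between two DAGs.

    Per unordered pair: a missing edge costs one insertion, an extra edge
    one deletion, and an edge present in both but reversed costs a single
    flip.
    """
    T = _binary(B_true)
    E = _binary(B_est)
    if T.shape != E.shape:
        raise ValueError("dimension mismatch between true and estimated graphs")
    dist = 0
    p = T.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            t = (T[i, j], T[j, i])
            e = (E[i, j], E[j, i])
            if t != e:
                dist += 1
    return dist


def edge_set(B: np.ndarray) -> set[tuple[int, int]]:
    """Directed edge set {(i, j)} of a weighted or binary adjacency."""
    A = _binary(B)
    return {(int(i), int(j)) for i, j in np.argwhere(A)}


def jaccard(E1, E2) -> float:
    """|E1 ∩ E2| / |E1 ∪ E2| over directed edges; two empty sets give 1."""
    s1 = edge_set(E1) if isinstance(E1, np.ndarray) else set(E1)
    s2 = edge_set(E2) if isinstance(E2, np.ndarray) else set(E2)
    union = s1 | s2
    if not union:
        return 1.0
    return len(s1 & s2) / len(union)


@dataclass
class HubReport:
    in_degree: np.ndarray
    out_degree: np.ndarray
    total_degree: np.ndarray
    mode: str
    threshold: float
    hubs: np.ndarray  # node indices flagged as hubs


def detect_hubs(B: np.ndarray, mode: str = "total") -> HubReport:
    """Flag nodes whose degree is at least two population standard
    deviations above the mean of the chosen degree sequence (in, out or
    total).  A degenerate sequence (sd = 0) yields no hubs: no node then
    exceeds the average.
    """
    A = _binary(B)
    indeg = A.sum(axis=0)
    outdeg = A.sum(axis=1)
    total = indeg + outdeg
    seq = {"in": indeg, "out": outdeg, "total": total}.get(mode)
    if seq is None:
        raise ValueError(f"mode must be 'in', 'out' or 'total'; got {mode!r}")
    mu = float(seq.mean())
    sd = float(seq.std())  # population sd
    thr = mu + 2.0 * sd
    hubs = np.flatnonzero(seq >= thr) if sd > 0 else np.array([], dtype=int)
    return HubReport(indeg, outdeg, total, mode, thr, hubs)


def _module_sizes(m: dict, labels: list) -> np.ndarray:
    return np.array([sum(1 for v in m.values() if v == lab) for lab in labels])


def module_flow_counts(
    B: np.ndarray, m: dict
) -> tuple[np.ndarray, list]:
    """M x M matrix of directed edge counts between modules; entry (A, B)
    counts edges whose source lies in module A and target in module B.
    Returns the count matrix and the sorted module-label list.
    """
    A = _binary(B)
    p = A.shape[0]
    missing = [i for i in range(p) if i not in m]
    if missing:
        raise ValueError(f"nodes without a module label: {missing}")
    labels = sorted(set(m.values()), key=str)
    idx = {lab: t for t, lab in enumerate(labels)}
    flows = np.zeros((len(labels), len(labels)), dtype=int)
    for i, j in np.argwhere(A):
        flows[idx[m[int(i)]], idx[m[int(j)]]] += 1
    return flows, labels


def hypergeometric_enrichment(
    flows: np.ndarray,
    m: dict,
    total_edges: int,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list]:
    """One-sided over-representation test per module block.

    For block (A, B) the population is the p(p-1) ordered node pairs, of
    which n_A * n_B (minus n_A when A = B, self-loops excluded) belong to
    the block; ``total_edges`` pairs are drawn and the block's observed
    flow is tested with P[X >= observed] under the hypergeometric law.
    BH-FDR is applied jointly across all M^2 blocks at ``alpha``.
    Returns (p-value matrix, significance flags, module labels).
    """
    labels = sorted(set(m.values()), key=str)
    sizes = _module_sizes(m, labels)
    p = len(m)
    population = p * (p - 1)
    M = len(labels)
    flows = np.asarray(flows)
    if flows.shape != (M, M):
        raise ValueError("flow matrix does not match the module map")
    if int(flows.sum()) != int(total_edges):
        raise ValueError("flow matrix total and total_edges disagree")
    pvals = np.ones((M, M))
    for a in range(M):
        for b in range(M):
            block = sizes[a] * sizes[b] - (sizes[a] if a == b else 0)
            obs = int(flows[a, b])
            if obs > block:
                raise ValueError(
                    f"block ({labels[a]}, {labels[b]}) observes {obs} edges "
                    f"but only {block} pairs exist"
                )
            pvals[a, b] = hypergeom.sf(obs - 1, population, block, total_edges)
    reject, *_ = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")
    return pvals, reject.reshape(M, M), labels


def common_distinct_patterns(
    E_list: list,
) -> tuple[set, list[set]]:
    """Common edges (intersection across all groups) and per-group
    distinctive edges (present in that group only)."""
    if len(E_list) < 2:
        raise ValueError("need at least 2 groups")
    sets = [edge_set(E) if isinstance(E, np.ndarray) else set(E) for E in E_list]
    common = set.intersection(*sets)
    distinct = []
    for k, s in enumerate(sets):
        others = set.union(*(t for j, t in enumerate(sets) if j != k))
        distinct.append(s - others)
    return common, distinct


def robustness_subsample(
    X_groups: list[np.ndarray],
    fractions: list[float],
    reps: int,
    estimator,
    rng: np.random.Generator,
    min_n: int = 10,
) -> pd.DataFrame:
    """Stability of detected edge counts under subsampling.

    For each fraction, rows are drawn without replacement within each
    group (preserving the group proportions), the estimator — a callable
    mapping a list of data matrices to a list of weighted adjacencies —
    is re-run ``reps`` times, and the mean and standard deviation of the
    per-group detected edge counts are reported in long format.
    """
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    records = []
    for frac in fractions:
        sizes = [int(round(frac * X.shape[0])) for X in X_groups]
        if any(s < min_n for s in sizes):
            warnings.warn(f"fraction {frac} yields groups below n={min_n}; skipped")
            continue
        counts = np.zeros((reps, len(X_groups)), dtype=int)
        for r in range(reps):
            subs = [
                X[rng.choice(X.shape[0], size=s, replace=False)]
                for X, s in zip(X_groups, sizes)
            ]
            B_hat = estimator(subs)
            counts[r] = [len(edge_set(B)) for B in B_hat]
        for k in range(len(X_groups)):
            records.append(
                {
                    "fraction": frac,
                    "group": k,
                    "mean_edges": float(counts[:, k].mean()),
                    "sd_edges": float(counts[:, k].std(ddof=1)) if reps > 1 else 0.0,
                    "reps": reps,
                }
            )
    return pd.DataFrame.from_records(records)
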