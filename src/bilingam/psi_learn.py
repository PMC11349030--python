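"""Association-network estimation by correlation-screened partial
correlations (psi-learning).

Full p-variable partial correlations are ill-posed when p approaches or
exceeds n.  The psi-learning device replaces the full conditioning set of a
pair (i, j) with a reduced set built from the top correlation-ranked
neighbours of i and j, giving a consistent high-dimensional surrogate for
the partial correlation (the "psi-score").  Edges are then called by a
Fisher-z test on the psi-scores with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PsiScoreMatrix",
    "default_cap",
    "screen_neighborhoods",
    "psi_scores",
    "psi_test",
    "fisher_z",
]

_ATANH_CLAMP = 1.0 - 1e-12


@dataclass
class PsiScoreMatrix:
    """Symmetric psi partial-correlation scores and per-pair conditioning sizes."""

    psi: np.ndarray  # p x p, symmetric, zero diagonal, entries in [-1, 1]
    cond_size: np.ndarray  # p x p int, |S_ij| actually used
    n: int


def default_cap(n: int) -> int:
    """Default neighbourhood / conditioning cap: floor(n / log n), at least 1."""
    return max(1, int(np.floor(n / np.log(n))))


def screen_neighborhoods(Z: np.ndarray, cap: int | None = None) -> list[np.ndarray]:
    """Rank, for each node, all other nodes by absolute marginal Pearson
    correlation and truncate at ``cap`` (default floor(n / log n)).
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if cap is None:
        cap = default_cap(n)
    if cap < 1:
        raise ValueError("cap must be >= 1")
    C = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(C, 0.0)
    absC = np.abs(C)
    nbrs = []
    for i in range(p):
        order = np.argsort(-absC[i], kind="stable")
        order = order[order != i]
        nbrs.append(order[:cap].astype(int))
    return nbrs


def _partial_corr(R: np.ndarray, ridge: float = 1e-6) -> float:
    """Partial correlation of variables 0 and 1 of correlation matrix ``R``
    given the rest, via inversion; adds a ridge when ill-conditioned.
    """
    try:
        cond = np.linalg.cond(R)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("ill-conditioned conditioning matrix; applying ridge 1e-6")
        R = R + ridge * np.eye(R.shape[0])
    Om = np.linalg.inv(R)
    return float(-Om[0, 1] / np.sqrt(Om[0, 0] * Om[1, 1]))


def psi_scores(
    Z: np.ndarray,
    neighborhoods: list[np.ndarray],
    cond_cap: int | None = None,
) -> PsiScoreMatrix:
    """psi_ij = sample partial correlation of (Z_i, Z_j) given
    S_ij = (nbrs(i) ∪ nbrs(j)) \\ {i, j}, with |S_ij| truncated to
    ``cond_cap`` (default floor(n / log n)) keeping the members most
    correlated with the pair.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if cond_cap is None:
        cond_cap = default_cap(n)
    C = np.corrcoef(Z, rowvar=False)
    absC = np.abs(C)
    psi = np.zeros((p, p))
    sizes = np.zeros((p, p), dtype=int)
    nbr_sets = [set(nb.tolist()) for nb in neighborhoods]
    for i in range(p):
        for j in range(i + 1, p):
            S = (nbr_sets[i] | nbr_sets[j]) - {i, j}
            S = np.asarray(sorted(S), dtype=int)
            if S.size > cond_cap:
                relevance = np.maximum(absC[i, S], absC[j, S])
                keep = np.argsort(-relevance, kind="stable")[:cond_cap]
                S = np.sort(S[keep])
            idx = np.concatenate(([i, j], S))
            r = _partial_corr(C[np.ix_(idx, idx)]) if S.size else float(C[i, j])
            r = float(np.clip(r, -1.0, 1.0))
            psi[i, j] = psi[j, i] = r
            sizes[i, j] = sizes[j, i] = S.size
    return PsiScoreMatrix(psi=psi, cond_size=sizes, n=n)


def fisher_z(scores: PsiScoreMatrix) -> np.ndarray:
    """Fisher z-score matrix: z_ij = sqrt(n - |S_ij| - 3) * atanh(psi_ij).

    |psi| = 1 is clamped just below 1 to keep z finite.
    """
    df = scores.n - scores.cond_size - 3
    if np.any(df[~np.eye(len(df), dtype=bool)] <= 0):
        raise ValueError("n - |S| - 3 must be positive for the Fisher test")
    r = scores.psi
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|psi| = 1 encountered; clamping before atanh")
        r = np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP)
    z = np.sqrt(np.maximum(df, 1)) * np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def _bh_edges(z: np.ndarray, alpha: float, correction: str) -> np.ndarray:
    p = z.shape[0]
    iu = np.triu_indices(p, k=1)
    pvals = 2.0 * norm.sf(np.abs(z[iu]))
    if correction == "fdr_bh":
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    elif correction == "none":
        reject = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    adj = np.zeros((p, p), dtype=np.int8)
    adj[iu[0][reject], iu[1][reject]] = 1
    return adj | adj.T


def psi_test(
    scores: PsiScoreMatrix,
    n: int | None = None,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> np.ndarray:
    """Edge calls from psi-scores: two-sided Fisher-z p-values with BH-FDR
    control at ``alpha``; returns the symmetric 0/1 adjacency E^d.
    """
    if n is not None and n != scores.n:
        scores = PsiScoreMatrix(scores.psi, scores.cond_size, n)
    z = fisher_z(scores)
    return _bh_edges(z, alpha, correction)
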