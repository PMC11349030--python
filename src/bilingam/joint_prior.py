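"""Joint (similarity-strengthened) association estimation across groups and
prior-matrix assembly.

Per-group Fisher z-score matrices are combined edge-wise by a
sample-size-weighted Stouffer meta-analysis; each group's evidence is then
linearly coupled to the meta signal before re-testing, which pulls edge
calls toward structure shared by the groups.  The union of a group's
distinct edge set E^d and its joint edge set E^c becomes the search-space
prior for the causal stage: entry -1 marks a pair whose directed status is
left to be estimated, entry 0 excludes both orientations.
"""

from __future__ import annotations

import warnings

import numpy as np

from .psi_learn import PsiScoreMatrix, _bh_edges, fisher_z

__all__ = ["meta_combine", "joint_edge_sets", "assemble_prior", "group_z_scores"]


def group_z_scores(score_list: list[PsiScoreMatrix]) -> list[np.ndarray]:
    """Fisher z matrices for each group's psi-scores."""
    return [fisher_z(s) for s in score_list]


def meta_combine(z_groups: list[np.ndarray], n_list: list[int]) -> np.ndarray:
    """Weighted Stouffer combination per edge:

        z_meta = sum_k w_k z_k / sqrt(sum_k w_k^2),   w_k = sqrt(n_k).
    """
    if len(z_groups) != len(n_list):
        raise ValueError("one sample size per group required")
    if len(z_groups) == 1:
        warnings.warn("single group: meta z-scores equal the group z-scores")
        return np.array(z_groups[0], copy=True)
    if any(n < 10 for n in n_list):
        raise ValueError("meta-analysis needs n_k >= 10 per group")
    w = np.sqrt(np.asarray(n_list, dtype=float))
    num = sum(wk * zk for wk, zk in zip(w, z_groups))
    return num / np.sqrt(np.sum(w**2))


def joint_edge_sets(
    z_groups: list[np.ndarray],
    z_meta: np.ndarray,
    lam: float = 1.0,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    n_list: list[int] | None = None,
) -> list[np.ndarray]:
    """Per-group similarity-strengthened edge sets E^c.

    Combined evidence z'_k = (z_k + lam * z_meta), renormalized to unit
    variance under the edge-wise null, is tested two-sided with BH-FDR at
    ``alpha``.  Because z_meta contains z_k itself, the null variance of
    the raw sum is 1 + lam^2 + 2 lam c_k with c_k = w_k / sqrt(sum w^2)
    (w_k = sqrt(n_k)); dividing by its square root keeps the joint test
    correctly sized.  lam = 0 recovers the distinct-only decision; lam = 1
    (default) gives equal weight to the group and the meta signal.
    """
    if lam < 0:
        raise ValueError("coupling weight lam must be >= 0")
    K = len(z_groups)
    if n_list is None:
        c = np.full(K, 1.0 / np.sqrt(K))  # equal group sizes
    else:
        w = np.sqrt(np.asarray(n_list, dtype=float))
        c = w / np.sqrt(np.sum(w**2))
    out = []
    for k, z in enumerate(z_groups):
        null_sd = np.sqrt(1.0 + lam**2 + 2.0 * lam * c[k])
        z_comb = (z + lam * z_meta) / null_sd
        out.append(_bh_edges(z_comb, alpha, correction))
    return out


def assemble_prior(E_d: np.ndarray, E_c: np.ndarray) -> np.ndarray:
    """Prior matrix over {0, -1}: -1 wherever the pair is in E^d ∪ E^c
    (either orientation), 0 elsewhere including the diagonal.
    """
    E_d = np.asarray(E_d)
    E_c = np.asarray(E_c)
    if E_d.shape != E_c.shape or E_d.shape[0] != E_d.shape[1]:
        raise ValueError("edge sets must be square and of matching dimension")
    for name, E in (("E_d", E_d), ("E_c", E_c)):
        if not np.array_equal(E, E.T):
            raise ValueError(f"{name} adjacency must be symmetric")
    union = (E_d != 0) | (E_c != 0)
    union |= union.T
    A = np.where(union, -1, 0).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A
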