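"""Marginal non-Gaussianity screening and Gaussianization.

Partial-correlation graph estimators assume (approximately) Gaussian
marginals.  The nonparanormal transform maps each column through its
Winsorized empirical CDF and the standard-normal quantile function,
rendering the marginal approximately Gaussian while preserving ranks.
The Anderson-Darling normality test quantifies how non-Gaussian each
column is before (and after) transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from statsmodels.stats.diagnostic import normal_ad

__all__ = ["ADScreenResult", "TransformedMatrix", "anderson_darling_screen", "npn_transform"]


@dataclass
class ADScreenResult:
    statistic: np.ndarray  # per-column A^2, NaN where non-testable
    pvalue: np.ndarray
    reject: np.ndarray  # boolean; False where non-testable
    testable: np.ndarray  # boolean; False for constant columns
    fraction_rejected: float  # over testable columns only


@dataclass
class TransformedMatrix:
    Z: np.ndarray  # n x p, unit sample sd per column
    delta: float  # Winsorization level applied to the ECDF
    columns: list[str] | None = None


def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.asarray(X, dtype=float), None


def anderson_darling_screen(X, alpha: float = 0.05) -> ADScreenResult:
    """Anderson-Darling test of normality (estimated mean and variance)
    applied to every column; constant columns are flagged non-testable and
    excluded from the rejection fraction.
    """
    A, _ = _as_array(X)
    n, p = A.shape
    if n < 8:
        raise ValueError("Anderson-Darling screen needs at least 8 observations")
    stat = np.full(p, np.nan)
    pval = np.full(p, np.nan)
    testable = np.ptp(A, axis=0) > 0
    for j in np.flatnonzero(testable):
        stat[j], pval[j] = normal_ad(A[:, j])
    reject = np.zeros(p, dtype=bool)
    reject[testable] = pval[testable] < alpha
    frac = float(reject[testable].mean()) if testable.any() else float("nan")
    return ADScreenResult(stat, pval, reject, testable, frac)


def npn_transform(X) -> TransformedMatrix:
    """Nonparanormal (Gaussian-copula marginal) transform.

    Per column: empirical CDF values rank/(n+1) (average ranks on ties) are
    Winsorized to [delta_n, 1 - delta_n] with

        delta_n = 1 / (4 n^{1/4} sqrt(pi log n)),

    mapped through the standard-normal quantile function, and rescaled to
    unit sample standard deviation (ddof=1).  The map is invariant to any
    strictly increasing transformation of a column.
    """
    A, cols = _as_array(X)
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    flat = np.flatnonzero(np.ptp(A, axis=0) == 0)
    if flat.size:
        names = [cols[j] if cols else str(j) for j in flat]
        raise ValueError(f"constant column(s) cannot be Gaussianized: {names}")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    U = rankdata(A, axis=0, method="average") / (n + 1.0)
    U = np.clip(U, delta, 1.0 - delta)
    Z = ndtri(U)
    Z /= Z.std(axis=0, ddof=1)
    return TransformedMatrix(Z=Z, delta=float(delta), columns=cols)
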