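"""Inter-rater reliability statistics for expert parameterisations.

Two standard coefficients qualify an expert panel before its thresholds and
importance weights are used:

* Cronbach's alpha -- internal consistency of the items (columns) across
  raters, ``alpha = n/(n-1) * (1 - sum(item variances)/variance(totals))``;
* Kendall's W -- rank concordance among raters, with mid-rank tie handling,
  the tie correction ``T = sum(t^3 - t)`` per rater, and the large-sample
  test ``chi2 = k (n - 1) W`` on ``n - 1`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ReliabilityResult:
    """A reliability coefficient with its test auxiliaries (where defined)."""

    statistic: str
    value: float
    n_raters: int
    n_items: int
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("rating matrix must be two-dimensional")
    if np.isnan(m).any():
        raise ValueError("rating matrix contains missing cells")
    k, n = m.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    return m


def cronbach_alpha(matrix) -> ReliabilityResult:
    """Cronbach's alpha of a raters x items matrix.

    Raters are rows (observations), items are columns.  Sample variances
    (``ddof=1``) are used throughout.  Raises when the total-score variance
    is zero, where the statistic is undefined.
    """
    m = _as_matrix(matrix)
    k, n = m.shape
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = n / (n - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(
        statistic="cronbach_alpha", value=float(alpha), n_raters=k, n_items=n
    )


def kendall_w(matrix, tie_correction: bool = True) -> ReliabilityResult:
    """Kendall's coefficient of concordance W of a raters x items matrix.

    Each rater's scores are converted to mid-ranks across the items;

        W = 12 S / (k^2 (n^3 - n) - k T)

    with ``S`` the sum of squared deviations of item rank-sums from their
    mean and ``T`` the tie correction (0 when ``tie_correction`` is off).
    The chi-square approximation requires at least 3 items.
    """
    m = _as_matrix(matrix)
    k, n = m.shape
    if n < 3:
        raise ValueError("Kendall's W chi-square test needs at least 3 items")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    if np.ptp(ranks, axis=1).min() == 0.0:
        raise ValueError("a rater assigned identical scores to every item; "
                         "ranking undefined")
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    correction = 0.0
    if tie_correction:
        for row in m:
            _, counts = np.unique(row, return_counts=True)
            correction += float((counts**3 - counts).sum())
    denom = k**2 * (n**3 - n) - k * correction
    if denom <= 0.0:
        raise ValueError("tie correction degenerate: every rater tied all items")
    w = 12.0 * s / denom
    chi2 = k * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return ReliabilityResult(
        statistic="kendall_w",
        value=float(w),
        n_raters=k,
        n_items=n,
        chi2=float(chi2),
        df=df,
        p_value=p,
    )
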