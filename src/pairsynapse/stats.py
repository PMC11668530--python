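"""Group comparisons with a normality/variance-gated choice of test.

Two groups are compared with an unpaired two-sided t-test when both pass
the Shapiro-Wilk normality test and an F test finds no difference in
variance (both at alpha = 0.05); otherwise the non-parametric
Mann-Whitney U test is used.  This mirrors standard practice in the
electrophysiology literature; no multiple-testing correction is applied
(variables are reported individually).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = ["GroupComparison", "compare_groups"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one two-group comparison."""

    variable: str
    group_a: list = field(default_factory=list)
    group_b: list = field(default_factory=list)
    test_used: str = ""  # unpaired_t | mann_whitney
    p_value: float = np.nan
    normality_p: tuple = (np.nan, np.nan)
    variance_p: float = np.nan
    mean_a: float = np.nan
    sem_a: float = np.nan
    mean_b: float = np.nan
    sem_b: float = np.nan
    median_a: float = np.nan
    iqr_a: tuple = (np.nan, np.nan)
    median_b: float = np.nan
    iqr_b: tuple = (np.nan, np.nan)


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = sstats.f.sf(f, dfa, dfb) if f >= 1 else sstats.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * p))


def compare_groups(
    a, b, variable: str = "", alpha: float = ALPHA
) -> GroupComparison:
    """Compare two value lists with the gated unpaired-t / Mann-Whitney rule.

    Parameters
    ----------
    a, b : array-like
        Group values (each n >= 3; NaNs are dropped).
    variable : str
        Name recorded in the result.

    Returns
    -------
    GroupComparison with the gate decisions, the two-sided p-value and
    mean +/- sem and median + IQR summaries per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 finite values")

    # identical constant groups: no distributional test is meaningful
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        norm_pa = norm_pb = np.nan
        var_p = 1.0
        test, p = "mann_whitney", 1.0
    else:
        norm_pa = float(sstats.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
        norm_pb = float(sstats.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
        var_p = _f_test(a, b)
        parametric = norm_pa > alpha and norm_pb > alpha and var_p > alpha
        if parametric:
            test = "unpaired_t"
            p = float(sstats.ttest_ind(a, b).pvalue)
        else:
            test = "mann_whitney"
            p = float(sstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        variable=variable,
        group_a=a.tolist(),
        group_b=b.tolist(),
        test_used=test,
        p_value=p,
        normality_p=(norm_pa, norm_pb),
        variance_p=var_p,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        median_a=float(qa[1]),
        iqr_a=(float(qa[0]), float(qa[2])),
        median_b=float(qb[1]),
        iqr_b=(float(qb[0]), float(qb[2])),
    )
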