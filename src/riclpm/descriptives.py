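"""Descriptive statistics: rank correlations, rank tests, median/IQR.

The Spearman interval uses the Fisher z transform with the rank-correlation
variance 1.06/(n-3); magnitudes are labelled small (|rho| <= 0.30), medium
(0.30 < |rho| <= 0.50) or large (> 0.50).

The Wilcoxon signed-rank test handles zero differences by the Pratt rule
(zeros are ranked with the rest, then dropped from the statistic) and ties
by average ranks.  For up to 25 nonzero differences the null distribution
of W+ is computed exactly by dynamic programming over the doubled ranks;
above that a tie-corrected normal approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SpearmanResult",
    "RankTestResult",
    "spearman_ci",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "median_iqr",
]

EXACT_LIMIT = 25  # nonzero differences; beyond this the normal approximation


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    label: str
    defined: bool = True


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    pvalue: float
    n: int
    method: str
    defined: bool = True


def _magnitude_label(rho: float) -> str:
    a = abs(rho)
    if a <= 0.30:
        return "small"
    if a <= 0.50:
        return "medium"
    return "large"


def spearman_ci(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation with Fisher-z CI and magnitude label.

    Pairs with a missing member are dropped (pairwise-complete); a constant
    vector leaves the correlation undefined (flagged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), float("nan"),
                              n, "", defined=False)
    rho = float(stats.spearmanr(x, y).statistic)
    z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    se = np.sqrt(1.06 / (n - 3))
    crit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return SpearmanResult(rho, float(lo), float(hi), n, _magnitude_label(rho))


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for W+ (doubled ranks, integers) by DP.

    The null assigns each nonzero difference an independent random sign;
    the distribution of the doubled positive-rank sum is built by
    polynomial convolution and is symmetric about half the total.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    lower = counts[: w2i + 1].sum()
    upper = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(before, after) -> RankTestResult:
    """Paired signed-rank test of before vs after (Pratt zeros, tie-aware).

    The statistic is W+ = sum of the ranks of positive differences
    (after - before), ranks taken over |differences| including zeros.
    All-zero differences leave the test undefined (flagged).
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(before) | np.isnan(after))
    d = (after - before)[keep]
    n = len(d)
    if n == 0 or np.all(d == 0):
        return RankTestResult(float("nan"), float("nan"), n, "undefined",
                              defined=False)
    ranks = stats.rankdata(np.abs(d))      # zeros included (Pratt), avg ties
    nz = d != 0
    w_plus = float(ranks[d > 0].sum())
    r_nz = ranks[nz]
    if nz.sum() <= EXACT_LIMIT:
        p = _signed_rank_exact_p(2 * r_nz, 2 * w_plus)
        return RankTestResult(w_plus, p, n, "exact")
    mean = r_nz.sum() / 2.0
    var = float(np.sum(r_nz**2)) / 4.0
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return RankTestResult(w_plus, p, n, "normal-approximation")


def mann_whitney(group_a, group_b) -> RankTestResult:
    """Independent-samples rank-sum test (two-sided).

    Exact null distribution for small tie-free samples, tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue),
                          len(a) + len(b), method)


def median_iqr(x, rule: str = "linear") -> tuple[float, float]:
    """Median and interquartile range under a configurable quartile rule.

    ``rule`` is any numpy percentile method name; the default linear
    interpolation matches mainstream statistical software.
    """
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("median of an empty vector is undefined")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method=rule)
    return float(med), float(q3 - q1)
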