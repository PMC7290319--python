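"""Agreement and hypothesis statistics: Bland–Altman, Spearman, Mann–Whitney.

Bland–Altman agreement between two diameter estimators uses the fixed
1.96 multiplier: bias = mean paired difference, limits of agreement
bias ± 1.96·SD(diff).  The *range* is the width of the limits
(loa_high − loa_low = 2·1.96·SD); pairs whose difference falls outside
the limits are counted as standing out of the optimal range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mean of paired differences, mm
    sd_diff: float  # sample SD of differences, mm
    loa_low: float  # bias - 1.96 * sd_diff
    loa_high: float  # bias + 1.96 * sd_diff
    loa_range: float  # loa_high - loa_low
    n_outside: int  # pairs with difference outside [loa_low, loa_high]
    n: int


def bland_altman(x_series, y_series) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired series (x − y differences)."""
    x = np.asarray(list(x_series), dtype=float)
    y = np.asarray(list(y_series), dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired series differ in length: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    low = bias - LOA_MULTIPLIER * sd
    high = bias + LOA_MULTIPLIER * sd
    outside = int(np.sum((d < low) | (d > high)))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=low,
        loa_high=high,
        loa_range=high - low,
        n_outside=outside,
        n=int(d.size),
    )


def spearman_rho(x_series, y_series) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(list(x_series), dtype=float)
    y = np.asarray(list(y_series), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant series")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Mann–Whitney U (for sample_a) with two-sided p.

    Exact p for small tie-free samples (both n ≤ 20), normal approximation
    with tie correction otherwise — scipy's "auto" policy.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
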