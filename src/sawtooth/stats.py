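"""Shared paired-comparison statistics.

Every condition contrast in the package (elongation-speed proxies, splicing
efficiency, circRNA index, mismatch rates, nucleosome signatures) reports
the same three quantities: the Hodges–Lehmann pseudo-median of the paired
differences, its 95% confidence interval from the Wilcoxon signed-rank
distribution, and the two-sided paired signed-rank p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

SMALL_SAMPLE_N = 6


@dataclass
class PairedComparison:
    """Summary of a paired two-condition contrast on per-unit differences."""

    n: int
    pseudo_median: float
    ci_low: float
    ci_high: float
    p_value: float
    small_sample: bool = False


def signed_rank_cdf(n: int) -> np.ndarray:
    """Null CDF of the signed-rank statistic W+ for sample size ``n``.

    Exact, by dynamic programming over the 2^n equally likely sign
    assignments (polynomial product over ranks); entry k is P(W+ <= k).
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    probs = counts / 2.0**n
    return np.cumsum(probs)


def signed_rank_quantile(alpha: float, n: int) -> int:
    """Largest integer k with P(W+ <= k) <= alpha under the null (-1 if none)."""
    if n <= 500:
        cdf = signed_rank_cdf(n)
        ok = np.nonzero(cdf <= alpha + 1e-12)[0]
        return int(ok[-1]) if ok.size else -1
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return int(np.floor(mean + sps.norm.ppf(alpha) * sd))


def hodges_lehmann(diffs: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Hodges–Lehmann pseudo-median of paired differences with its
    signed-rank confidence interval (median of Walsh averages; interval
    bounds are order statistics of the Walsh averages at the signed-rank
    critical values, as in R's ``wilcox.test(conf.int=TRUE)``)."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n == 0:
        return (np.nan, np.nan, np.nan)
    walsh = (d[:, None] + d[None, :]) / 2.0
    walsh = np.sort(walsh[np.triu_indices(n)])
    pm = float(np.median(walsh))
    m = len(walsh)
    alpha = 1.0 - conf
    c = signed_rank_quantile(alpha / 2.0, n)
    # CI = [W_(c+1), W_(M-c)] in 1-based order statistics of the Walsh
    # averages; P(lower bound exceeds the true location) = P(W+ <= c) <= a/2.
    lo_idx = max(c, 0) if c >= 0 else 0
    hi_idx = m - c - 1 if c >= 0 else m - 1
    if lo_idx > hi_idx:
        return (pm, float(walsh[0]), float(walsh[-1]))
    return (pm, float(walsh[lo_idx]), float(walsh[hi_idx]))


def paired_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p for condition B vs A.

    Zero differences are dropped (Wilcoxon's treatment); ties get average
    ranks. Exact null distribution when the reduced sample is small and
    tie-free, otherwise the normal approximation.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


def compare_paired(
    a: np.ndarray, b: np.ndarray, conf: float = 0.95
) -> PairedComparison:
    """Full paired contrast of per-unit values ``b`` vs ``a``.

    Units with a non-finite value in either condition are dropped pairwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 1:
        raise ValueError("no valid pairs to compare")
    small = n < SMALL_SAMPLE_N
    if small:
        warnings.warn(
            f"only {n} valid pairs; signed-rank p-value is unreliable", stacklevel=2
        )
    pm, lo, hi = hodges_lehmann(b - a, conf=conf)
    p = paired_wilcoxon_p(a, b)
    return PairedComparison(n, pm, lo, hi, p, small_sample=small)
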