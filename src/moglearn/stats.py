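"""Wilcoxon signed-rank test and multiple-testing adjustment.

The exact two-sided p-value is computed from the conditional permutation
distribution of the positive-rank sum (dynamic programming over doubled
midranks, so ties are handled exactly) for n <= 25 pairs; larger samples
use the normal approximation with Pratt zero handling, tie correction and
a continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_EXACT_LIMIT = 25


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (positive-rank sum)
    p_value: float
    n_used: int  # nonzero differences entering the statistic
    method: str  # "exact" | "normal"


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact tail probabilities by DP over the 2^n sign assignments.

    Ranks are doubled so midranks become integers; the distribution of the
    doubled positive-rank sum is built by convolution.
    """
    doubled = np.round(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2.0 * w_plus))
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(a, b=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    With one argument, ``a`` is the vector of paired differences.  Zero
    differences are handled by the Pratt method: zeros participate in the
    ranking of absolute values and are then discarded.  All differences
    zero gives p = 1.
    """
    d = np.asarray(a, dtype=float) if b is None else np.asarray(a, float) - np.asarray(b, float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a 1-D vector of paired differences")
    if not np.isfinite(d).all():
        raise ValueError("non-finite paired differences")
    nonzero = d != 0
    if not nonzero.any():
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, method="exact")

    # Pratt: rank |d| including zeros, then drop the zeros
    ranks_all = _midranks(np.abs(d))
    ranks = ranks_all[nonzero]
    signs = np.sign(d[nonzero])
    w_plus = float(ranks[signs > 0].sum())
    n = int(nonzero.sum())

    if n <= _EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")

    mean = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(w_plus, 1.0, n, "normal")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, p, n, "normal")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Per-metric paired comparison between two configurations."""

    metrics: list
    statistics: np.ndarray
    p_values: np.ndarray
    adjusted_p_values: np.ndarray
    reject: np.ndarray  # adjusted p < alpha
    alpha: float

    def as_dict(self) -> dict:
        return {
            m: {
                "statistic": float(s),
                "p_value": float(p),
                "adjusted_p_value": float(q),
                "reject": bool(r),
            }
            for m, s, p, q, r in zip(
                self.metrics, self.statistics, self.p_values,
                self.adjusted_p_values, self.reject,
            )
        }


def wilcoxon_compare(paired_a, paired_b, metrics, alpha: float = 0.05) -> ComparisonResult:
    """Paired Wilcoxon test per metric with BH adjustment across metrics.

    ``paired_a`` and ``paired_b`` are dicts (or DataFrame-likes) mapping
    metric name -> equal-length vectors of paired observations.
    """
    stats_, pvals = [], []
    for m in metrics:
        res = wilcoxon_signed_rank(np.asarray(paired_a[m]), np.asarray(paired_b[m]))
        stats_.append(res.statistic)
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    adj = bh_adjust(pvals)
    return ComparisonResult(
        metrics=list(metrics),
        statistics=np.asarray(stats_),
        p_values=pvals,
        adjusted_p_values=adj,
        reject=adj < alpha,
        alpha=alpha,
    )
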