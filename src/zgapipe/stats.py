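"""Shared statistics: Wilcoxon rank-sum comparison with effect size r.

The effect size is the standard r = |z| / sqrt(n1 + n2), with z taken from
the tie-corrected normal approximation of the Mann-Whitney U statistic with
continuity correction. The p-value is exact (full permutation null) when
both groups have ≤ 8 tie-free observations, and the tie-corrected normal
approximation otherwise, so small-group p-values match exhaustive
enumeration while large groups stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "ranksum_r_effect"]

_EXACT_MAX = 8


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    z_value: float
    p_value: float
    r_effect: float


def _tie_corrected_z(u: float, a: np.ndarray, b: np.ndarray) -> float:
    """z of the Mann-Whitney U under the tie-corrected normal null, with
    continuity correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    return float((diff - cc) / np.sqrt(var))


def ranksum_r_effect(values_a, values_b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test with effect size r = |z|/sqrt(N)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = a.size * b.size / 2.0
        return GroupComparison(label_a, label_b, a.size, b.size, u, 0.0, 1.0, 0.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= _EXACT_MAX and b.size <= _EXACT_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    z = _tie_corrected_z(float(res.statistic), a, b)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        z_value=z,
        p_value=float(min(res.pvalue, 1.0)),
        r_effect=float(abs(z) / np.sqrt(a.size + b.size)),
    )
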