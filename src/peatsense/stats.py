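"""Rank-based tests in the conventions of R's cor.test / wilcox.test.

Spearman correlations are reported with the S statistic (the sum of squared
rank differences) alongside rho; two-group comparisons use the rank-sum W in
the `wilcox.test` convention, which equals the Mann–Whitney U of the first
group and ranges over [0, n_a * n_b]. Kruskal–Wallis (tie-corrected H against
chi-squared) and pairwise Wilcoxon with Bonferroni adjustment cover the
multi-class comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "spearman",
    "spearman_rho_from_s",
    "rank_sum_w",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
]

#: Largest n_a * n_b for which the tie-free rank-sum p is computed exactly.
EXACT_RANKSUM_LIMIT = 400


@dataclass(frozen=True)
class RankTestResult:
    statistic_name: str          # one of S, rho, W, H
    statistic_value: float
    n_or_group_sizes: tuple[int, ...]
    p_value: float
    adjustment: str = "none"     # none | bonferroni
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho_from_s(s: float, n: int) -> float:
    """Invert the tie-free S statistic: rho = 1 - 6 S / (n (n^2 - 1))."""
    if n < 2:
        raise ValueError("need n >= 2")
    return 1.0 - 6.0 * s / (n * (n**2 - 1))


def spearman(x, y) -> RankTestResult:
    """Spearman rank correlation with the S statistic.

    Ranks use mid-ranks for ties; S = sum (rank_x - rank_y)^2. Without ties
    rho comes from the S formula, with ties from Pearson on the ranks (the
    two agree exactly when tie-free). Two-sided p via the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx, ry = _ranks(x), _ranks(y)
    s = float(np.sum((rx - ry) ** 2))
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if has_ties:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rho = spearman_rho_from_s(s, n)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return RankTestResult("rho", rho, (n,), p, extra={"S": s})


def rank_sum_w(a, b) -> RankTestResult:
    """Two-group rank-sum test with W in the `wilcox.test` convention.

    W = (sum of pooled ranks of group a) - n_a(n_a+1)/2, i.e. the
    Mann–Whitney U of group a, in [0, n_a * n_b]. The two-sided p is exact
    for small tie-free samples (n_a * n_b <= 400) and otherwise uses the
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _ranks(pooled)
    w = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_RANKSUM_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult("W", w, (a.size, b.size), float(res.pvalue),
                          extra={"method": method})


def kruskal_wallis(groups: list) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H with chi-squared p, df = k - 1.

    All-identical data leaves H undefined; that is reported (NaN statistic,
    NaN p) rather than raised, since screening loops must keep going.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return RankTestResult("H", float("nan"), sizes, float("nan"),
                              extra={"df": len(groups) - 1, "undefined": True})
    h, p = sps.kruskal(*arrays)
    return RankTestResult("H", float(h), sizes, float(p),
                          extra={"df": len(groups) - 1, "undefined": False})


def pairwise_wilcoxon_bonferroni(groups: dict[str, list]) -> pd.DataFrame:
    """All pairwise rank-sum tests with Bonferroni-adjusted p-values.

    Returns a symmetric label-indexed matrix of adjusted p-values
    (p_adj = min(1, p * m) with m = k(k-1)/2 comparisons); the diagonal is
    NaN.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if len(np.asarray(groups[lab])) == 0:
            raise ValueError(f"group {lab!r} is empty")
    m = len(labels) * (len(labels) - 1) // 2
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            p_adj = min(1.0, rank_sum_w(groups[la], groups[lb]).p_value * m)
            mat.loc[la, lb] = mat.loc[lb, la] = p_adj
    return mat
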