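"""Nonparametric repeated-measures statistics.

Small-sample venous-flow indices call for rank-based tests: the Friedman
omnibus test over complete subject x condition blocks, Conover's pairwise
post-hoc comparisons on the within-block ranks, Benjamini-Hochberg FDR
adjustment of the pairwise p values, and median [range] descriptives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

__all__ = [
    "GroupTable",
    "TestResult",
    "friedman_test",
    "durbin_conover_pairs",
    "fdr_adjust",
    "median_range",
    "friedman_with_posthoc",
]


@dataclass
class GroupTable:
    """n_subjects x k_conditions matrix of one scalar index, complete blocks."""

    values: np.ndarray
    condition_labels: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if np.isnan(self.values).any():
            raise ValueError("missing cells: complete blocks required")
        self.condition_labels = tuple(self.condition_labels)
        if len(self.condition_labels) != k:
            raise ValueError("condition_labels length mismatch")
        if not self.subject_ids:
            self.subject_ids = tuple(f"S{i + 1:02d}" for i in range(n))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    pairwise: list = field(default_factory=list)  # (pair, raw p, adjusted p)


def _block_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sst.rankdata, 1, values)  # average ranks on ties


def friedman_test(table: GroupTable) -> TestResult:
    """Tie-corrected Friedman chi-square test on complete blocks.

    Uses the rank-sum form T = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C)
    with A = sum of squared within-block ranks and C = n k (k+1)^2 / 4, which
    reduces to the classic statistic without ties; df = k - 1, p from the
    chi-square upper tail.  All-tied tables give statistic 0 and p = 1.
    """
    r = _block_ranks(table.values)
    n, k = table.n, table.k
    rank_sums = r.sum(axis=0)
    a = float((r**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every block fully tied
        return TestResult(statistic=0.0, df=k - 1, p_value=1.0)
    stat = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(sst.chi2.sf(stat, df=k - 1))
    return TestResult(statistic=stat, df=k - 1, p_value=p)


def durbin_conover_pairs(table: GroupTable) -> list[tuple[tuple[str, str], float]]:
    """Conover's post-hoc pairwise comparisons after a Friedman test.

    From the within-block ranks with column sums R_j, the pairwise statistic
    is t = |R_j - R_l| / sqrt(2 (n A - sum_j R_j^2) / ((n-1)(k-1))) referred
    to a t distribution with (n-1)(k-1) degrees of freedom (two-sided).
    Identical columns give statistic 0 and p = 1; the p values are symmetric
    in the order of the pair.
    """
    r = _block_ranks(table.values)
    n, k = table.n, table.k
    rank_sums = r.sum(axis=0)
    a = float((r**2).sum())
    var_term = 2.0 * (n * a - float((rank_sums**2).sum())) / ((n - 1) * (k - 1))
    df = (n - 1) * (k - 1)
    out = []
    for j in range(k):
        for l in range(j + 1, k):
            diff = abs(rank_sums[j] - rank_sums[l])
            if var_term <= 0:
                # zero error variance: blocks rank the conditions identically,
                # so any rank-sum difference is infinitely many SEs from zero
                p = 1.0 if diff == 0 else 0.0
            else:
                tval = diff / np.sqrt(var_term)
                p = float(2.0 * sst.t.sf(tval, df=df))
            pair = (table.condition_labels[j], table.condition_labels[l])
            out.append((pair, min(p, 1.0)))
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.  Never decreases any
    p value and is idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max) descriptives."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(np.median(v)), float(v.min()), float(v.max())


def friedman_with_posthoc(table: GroupTable) -> TestResult:
    """Friedman omnibus plus FDR-adjusted Conover pairwise comparisons."""
    res = friedman_test(table)
    pairs = durbin_conover_pairs(table)
    raw = [p for _, p in pairs]
    adj = fdr_adjust(raw)
    res.pairwise = [(pair, p, float(q)) for (pair, p), q in zip(pairs, adj)]
    return res
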