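"""Univariable cohort statistics.

Thin, convention-pinned wrappers over the standard nonparametric tests
used for clinical baseline tables:

* Pearson chi-square WITHOUT continuity correction for r x c contingency
  tables, switching to Fisher's exact test (two-sided, sum of tables at
  most as probable as observed) when the table is 2x2 and any expected
  cell count is below 5;
* Mann-Whitney U with midranks and a tie-corrected normal approximation
  (no continuity correction);
* the Jonckheere-Terpstra ordered-trend test with tie-corrected null
  moments (implemented here; not available in scipy);
* Spearman rank correlation.

Exact/enumeration p-values are deliberately not used at analysis time:
cohort sizes in scope make the normal approximations adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyResult",
    "RankTestResult",
    "TrendTestResult",
    "contingency_test",
    "mann_whitney_u",
    "jonckheere_terpstra",
    "spearman",
]


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float | None  # chi-square value; None for Fisher
    df: int | None
    p_two_sided: float
    test_used: str  # pearson | fisher
    expected_min: float


@dataclass(frozen=True)
class RankTestResult:
    u: float
    z: float
    p_two_sided: float
    tied: bool = False


@dataclass(frozen=True)
class TrendTestResult:
    jt_statistic: float
    mean_h0: float
    var_h0: float
    z: float
    p_two_sided: float


def contingency_test(table) -> ContingencyResult:
    """Chi-square or Fisher's exact test of an r x c count table.

    Decision rule: Fisher's exact (2x2 only) when any expected count is
    below 5; otherwise Pearson chi-square without continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2D array of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    expected = stats.contingency.expected_freq(t)
    exp_min = float(expected.min())
    if t.shape == (2, 2) and exp_min < 5:
        p = float(stats.fisher_exact(t.astype(int))[1])
        return ContingencyResult(None, None, p, "fisher", exp_min)
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(float(chi2), int(dof), float(p), "pearson", exp_min)


def mann_whitney_u(x, y) -> RankTestResult:
    """Mann-Whitney U from midrank sums with tie-corrected normal p.

    U counts pairs where an x-observation exceeds a y-observation (ties
    half).  Identical constant samples yield p = 1 by convention (flagged
    via ``tied``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return RankTestResult(u=u, z=0.0, p_two_sided=1.0, tied=True)
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankTestResult(u=u, z=float(z), p_two_sided=float(min(p, 1.0)))


def _mw_count(x, y) -> float:
    """Number of (x_i, y_j) pairs with x_i < y_j, ties counted half."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x < y).sum() + 0.5 * (x == y).sum())


def jonckheere_terpstra(groups) -> TrendTestResult:
    """Jonckheere-Terpstra test for an ordered trend across >= 3 groups.

    JT sums the pairwise Mann-Whitney counts over ordered group pairs;
    large JT means values increase with group order.  The z statistic uses
    the tie-corrected null mean and variance; p is two-sided.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 3:
        raise ValueError("need >= 3 ordered groups; use mann_whitney_u for two")
    if any(len(g) == 0 for g in samples):
        raise ValueError("all groups must be non-empty")
    jt = sum(_mw_count(samples[i], samples[j]) for i, j in combinations(range(len(samples)), 2))

    ni = np.array([len(g) for g in samples], dtype=float)
    N = ni.sum()
    pooled = np.concatenate(samples)
    _, tj = np.unique(pooled, return_counts=True)
    tj = tj.astype(float)
    mean = (N**2 - (ni**2).sum()) / 4.0
    v1 = (
        N * (N - 1) * (2 * N + 5)
        - (ni * (ni - 1) * (2 * ni + 5)).sum()
        - (tj * (tj - 1) * (2 * tj + 5)).sum()
    ) / 72.0
    v2 = (
        (ni * (ni - 1) * (ni - 2)).sum()
        * (tj * (tj - 1) * (tj - 2)).sum()
        / (36.0 * N * (N - 1) * (N - 2))
    )
    v3 = (ni * (ni - 1)).sum() * (tj * (tj - 1)).sum() / (8.0 * N * (N - 1))
    var = v1 + v2 + v3
    if var <= 0:
        return TrendTestResult(jt, mean, 0.0, 0.0, 1.0)
    z = (jt - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendTestResult(float(jt), float(mean), float(var), float(z), float(min(p, 1.0)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with the t-approximation p.

    Raises ValueError when either ranking has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples of length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a ranking: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
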