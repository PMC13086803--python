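"""Voxel-based lesion-symptom mapping (VLSM).

Mass-univariate comparison of an outcome score between subjects with and
without a lesion at each voxel, using the classical pooled-variance
two-sample t statistic, with

* minimum-overlap filtering (voxels lesioned in fewer than ``min_overlap``
  subjects, or non-lesioned in fewer than ``min_per_group``, are not
  tested), and
* familywise-error control by the permutation distribution of the maximum
  |t| over tested voxels: the outcome vector is permuted across subjects
  while the lesion geometry stays fixed, preserving the spatial
  correlation structure of the lesion maps.

FWE-corrected p-values use the (k+1)/(N+1) convention that includes the
observed statistic, so p is never 0 and the test is exactly valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort_io import TOTAL, Cohort
from .frequency_maps import FrequencyMap, overlap_counts

__all__ = [
    "VLSMParams",
    "VLSMResult",
    "inclusion_mask",
    "pooled_t",
    "permutation_threshold",
    "fwe_p_values",
    "run_vlsm",
]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class VLSMParams:
    min_overlap: int = 3
    n_permutations: int = 2000
    alpha: float = 0.05
    outcome: str = "gose"
    seed: int = 0
    min_per_group: int = 2
    side: str = "two"  # two | greater | less

    def __post_init__(self) -> None:
        if self.min_overlap < 1 or self.n_permutations < 1:
            raise ValueError("min_overlap and n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.side not in ("two", "greater", "less"):
            raise ValueError("side must be two|greater|less")


@dataclass
class VLSMResult:
    grid_shape: tuple[int, int, int]
    tested_mask: np.ndarray  # bool, 3D
    t_map: np.ndarray  # float, 3D; NaN outside tested voxels
    df_map: np.ndarray  # int, 3D; -1 outside
    null_max_t: np.ndarray  # (n_permutations,)
    critical_t: float
    significant_mask: np.ndarray  # bool, 3D
    fwe_p_map: np.ndarray  # float, 3D; NaN outside
    n_subjects: int
    n_excluded_missing_outcome: int
    degenerate_mask: np.ndarray | None = None

    @property
    def n_tested(self) -> int:
        return int(self.tested_mask.sum())

    @property
    def n_significant(self) -> int:
        return int(self.significant_mask.sum())


def inclusion_mask(counts: FrequencyMap, params: VLSMParams) -> np.ndarray:
    """Voxels eligible for testing: lesioned in >= min_overlap subjects and
    non-lesioned in >= min_per_group subjects."""
    c = counts.counts
    return (c >= params.min_overlap) & (c <= counts.n_subjects - params.min_per_group)


def pooled_t(outcomes_lesioned, outcomes_rest) -> tuple[float, int]:
    """Classical two-sample pooled-variance t and its degrees of freedom.

    Positive t means the lesioned group has the higher mean outcome.
    Raises ValueError on groups smaller than 2 or zero pooled variance
    (such voxels are degenerate and excluded from mapping).
    """
    a = np.asarray(outcomes_lesioned, dtype=float)
    b = np.asarray(outcomes_rest, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= _VAR_EPS:
        raise ValueError("zero pooled variance: degenerate voxel")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def _t_matrix(L: np.ndarray, Y: np.ndarray, dtype=np.float64) -> np.ndarray:
    """t statistics for every (voxel, outcome-column) pair.

    L: (n, V) lesion indicator; Y: (n, P) outcome columns.  Returns (V, P)
    with NaN where the pooled variance is degenerate.  The heavy work is
    two matrix products, so permutations vectorize through BLAS; float32
    is offered for the permutation null, where ~1e-3 accuracy of t is
    ample relative to the Monte-Carlo error of the threshold.
    """
    n = L.shape[0]
    Y = np.asarray(Y, dtype=dtype)
    Lf = L.astype(dtype)
    n1 = Lf.sum(axis=0)  # (V,)
    n0 = n - n1
    s1 = Lf.T @ Y  # (V, P)
    q1 = Lf.T @ (Y * Y)
    tot = Y.sum(axis=0)  # (P,)
    totq = (Y * Y).sum(axis=0)
    # zero-variance groups cancel catastrophically in the sum-of-squares
    # identity, so the degeneracy cutoff must scale with the outcome
    # magnitude and the working precision
    rel = 1e-5 if dtype == np.float32 else 1e-10
    eps = np.maximum(_VAR_EPS, rel * (totq / n + 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1[:, None]
        m0 = (tot[None, :] - s1) / n0[:, None]
        ss1 = q1 - n1[:, None] * m1 * m1
        ss0 = (totq[None, :] - q1) - n0[:, None] * m0 * m0
        sp2 = (ss1 + ss0) / (n - 2)
        t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0)[:, None])
    t[sp2 <= eps[None, :]] = np.nan
    return t


def _stat(t: np.ndarray, side: str) -> np.ndarray:
    if side == "two":
        return np.abs(t)
    if side == "greater":
        return t
    return -t


def permutation_threshold(
    cohort_or_L,
    tested_mask: np.ndarray,
    params: VLSMParams,
    outcomes: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Null distribution of the maximum statistic and the FWE threshold.

    Accepts either a Cohort (outcome taken from ``params.outcome``,
    subjects with missing outcome excluded) or a prebuilt (n, V) lesion
    matrix together with ``outcomes``.  Returns (null_max, critical value
    at level alpha under the (k+1)/(N+1) convention); critical value is
    +inf when no value satisfies the level (nothing can be significant).
    """
    if isinstance(cohort_or_L, Cohort):
        L, y, _ = _lesion_matrix_and_outcome(cohort_or_L, params)
        Lt = L[:, np.asarray(tested_mask).reshape(-1)]
    else:
        Lt = np.asarray(cohort_or_L)
        y = np.asarray(outcomes, dtype=float)
    if Lt.shape[1] == 0:
        raise ValueError("tested mask is empty")
    rng = np.random.default_rng(params.seed)
    null_max = _null_max_distribution(Lt, y, params, rng)
    crit = _critical_value(null_max, params)
    return null_max, crit


def _null_max_distribution(
    Lt: np.ndarray, y: np.ndarray, params: VLSMParams, rng: np.random.Generator
) -> np.ndarray:
    n = len(y)
    out = np.empty(params.n_permutations, dtype=float)
    chunk = max(1, min(256, int(2e8 // max(1, 8 * Lt.shape[1]))))
    done = 0
    while done < params.n_permutations:
        m = min(chunk, params.n_permutations - done)
        Y = np.empty((n, m), dtype=np.float32)
        for j in range(m):
            Y[:, j] = y[rng.permutation(n)]
        stat = _stat(_t_matrix(Lt, Y, dtype=np.float32), params.side)
        maxes = np.nanmax(stat, axis=0).astype(np.float64)
        for j in range(m):
            while not np.isfinite(maxes[j]):
                # every tested voxel degenerate under this permutation: redraw
                logger.info("redrawing a fully degenerate permutation")
                yj = y[rng.permutation(n)][:, None]
                maxes[j] = np.nanmax(_stat(_t_matrix(Lt, yj), params.side))
        out[done : done + m] = maxes
        done += m
    return out


def fwe_p_values(null_max: np.ndarray, stats_obs: np.ndarray, n_permutations: int) -> np.ndarray:
    """FWE-corrected p per statistic: (1 + #{null >= stat}) / (N + 1).

    A relative tie tolerance keeps permutations that reproduce the observed
    statistic exactly (an atom of the discrete null) counted as >= even
    when the null was evaluated at lower precision.
    """
    stats_obs = np.atleast_1d(np.asarray(stats_obs, dtype=float))
    tol = 1e-5 * np.maximum(1.0, np.abs(stats_obs))
    ge = np.array([(null_max >= s - t).sum() for s, t in zip(stats_obs, tol)])
    return (1.0 + ge) / (n_permutations + 1.0)


def _critical_value(null_max: np.ndarray, params: VLSMParams) -> float:
    """Smallest observed null maximum c with (1 + #{null >= c})/(N+1) <= alpha."""
    N = len(null_max)
    srt = np.sort(null_max)[::-1]
    # p-value of candidate srt[k-1] (k-th largest) is (1 + k') / (N+1) with
    # k' the count of null values >= it; scan from the top
    counts = np.arange(1, N + 1)
    # handle ties: count of values >= srt[i] is the last index with that value
    ge = np.searchsorted(-srt, -srt, side="right")
    p = (1.0 + ge) / (N + 1.0)
    ok = np.nonzero(p <= params.alpha)[0]
    if len(ok) == 0:
        return float("inf")
    return float(srt[ok[-1]])


def _lesion_matrix_and_outcome(cohort: Cohort, params: VLSMParams):
    keep = [s for s in cohort.subjects if getattr(s, params.outcome, None) is not None]
    n_excl = len(cohort) - len(keep)
    if n_excl:
        logger.info("excluding %d subjects with missing %s", n_excl, params.outcome)
    if len(keep) < 2 * params.min_per_group:
        raise ValueError("too few subjects with the outcome present")
    sub = Cohort(cohort.grid, keep)
    L = sub.lesion_matrix(TOTAL)
    y = np.array([float(getattr(s, params.outcome)) for s in keep])
    return L, y, n_excl


def run_vlsm(cohort: Cohort, params: VLSMParams | None = None) -> VLSMResult:
    """Full VLSM analysis: inclusion mask, observed t-map, permutation null,
    FWE threshold, significance mask and FWE-corrected p-map.

    An empty tested mask yields a structured "nothing testable" result
    rather than an exception.
    """
    params = params or VLSMParams()
    L, y, n_excl = _lesion_matrix_and_outcome(cohort, params)
    n = len(y)
    shape = cohort.grid.shape
    counts3d = L.sum(axis=0).reshape(shape).astype(np.int32)
    fmap = FrequencyMap(cohort.grid, counts3d, n, "vlsm", TOTAL)
    tested3d = inclusion_mask(fmap, params)
    flat_tested = tested3d.reshape(-1)

    t_map = np.full(shape, np.nan)
    df_map = np.full(shape, -1, dtype=np.int32)
    fwe_p = np.full(shape, np.nan)
    sig = np.zeros(shape, dtype=bool)
    degen = np.zeros(shape, dtype=bool)

    if not flat_tested.any():
        logger.warning("no voxel satisfies the overlap criteria; nothing testable")
        return VLSMResult(
            shape, tested3d, t_map, df_map, np.empty(0), float("inf"), sig, fwe_p,
            n, n_excl, degen,
        )

    Lt = L[:, flat_tested]
    t_obs = _t_matrix(Lt, y[:, None])[:, 0]
    degen_flat = ~np.isfinite(t_obs)
    if degen_flat.any():
        logger.info("%d degenerate voxels excluded from mapping", int(degen_flat.sum()))
    degen.reshape(-1)[np.nonzero(flat_tested)[0][degen_flat]] = True
    # degenerate voxels are excluded from the tested set (and the null)
    tested_idx = np.nonzero(flat_tested)[0][~degen_flat]
    tested3d = np.zeros(shape, dtype=bool)
    tested3d.reshape(-1)[tested_idx] = True
    Lt = Lt[:, ~degen_flat]
    t_obs = t_obs[~degen_flat]
    if Lt.shape[1] == 0:
        return VLSMResult(
            shape, tested3d, t_map, df_map, np.empty(0), float("inf"), sig, fwe_p,
            n, n_excl, degen,
        )

    rng = np.random.default_rng(params.seed)
    null_max = _null_max_distribution(Lt, y, params, rng)
    crit = _critical_value(null_max, params)

    stat_obs = _stat(t_obs, params.side)
    p = fwe_p_values(null_max, stat_obs, params.n_permutations)

    t_map.reshape(-1)[tested_idx] = t_obs
    df_map.reshape(-1)[tested_idx] = n - 2
    fwe_p.reshape(-1)[tested_idx] = p
    sig.reshape(-1)[tested_idx] = p <= params.alpha
    return VLSMResult(
        shape, tested3d, t_map, df_map, null_max, crit, sig, fwe_p, n, n_excl, degen
    )
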