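"""Proportional-odds ordinal regression of the 3-level functional outcome.

The model is the cumulative-logit proportional-odds model

    logit P(Y <= k | x) = alpha_k - x' beta,      alpha_1 < alpha_2 < ...

fitted by damped Newton iterations on the multinomial log-likelihood with
analytic gradient and Hessian; the parameter covariance is the inverse
observed information at the optimum.  The outcome category order is
inverted (good recovery GOSE 7-8 -> level 1, severe disability GOSE 1-4 ->
level 3) so that a positive beta means higher odds of a WORSE outcome, and
the GCS score enters inverted (15 - GCS) for the same reason.  Effects are
reported as odds ratios exp(beta) with Wald 95% confidence intervals, and
model fit as McFadden's pseudo R^2 = 1 - ll / ll_null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort_io import Cohort

__all__ = [
    "COVARIATES",
    "MODEL_PRESETS",
    "ModelSpec",
    "OrdinalModelFit",
    "EffectEstimate",
    "ConvergenceError",
    "SeparationError",
    "build_design",
    "fit_proportional_odds",
    "effect_table",
    "mcfadden_r2",
]

_Z95 = 1.959964

COVARIATES = (
    "age",
    "pupil_abnormality",
    "gcs_inverted",
    "days_to_mri",
    "total_volume_cm3",
    "hemorrhagic_volume_cm3",
    "tai_volume_cm3",
    "tai_trondheim_grade",
)

#: The four preset covariate sets: age, pupil abnormality, inverted GCS and
#: days to MRI in every model; total (1, 2) or hemorrhagic (3, 4) contusion
#: volume; TAI volume (1, 3) or Trondheim TAI grade (2, 4).
MODEL_PRESETS = {
    "model1": ("age", "pupil_abnormality", "gcs_inverted", "days_to_mri",
               "total_volume_cm3", "tai_volume_cm3"),
    "model2": ("age", "pupil_abnormality", "gcs_inverted", "days_to_mri",
               "total_volume_cm3", "tai_trondheim_grade"),
    "model3": ("age", "pupil_abnormality", "gcs_inverted", "days_to_mri",
               "hemorrhagic_volume_cm3", "tai_volume_cm3"),
    "model4": ("age", "pupil_abnormality", "gcs_inverted", "days_to_mri",
               "hemorrhagic_volume_cm3", "tai_trondheim_grade"),
}


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the model; order is preserved in reports."""

    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("at least one covariate required")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass
class OrdinalModelFit:
    covariate_names: tuple[str, ...]
    beta: np.ndarray
    cutpoints: np.ndarray
    cov_params: np.ndarray  # (K-1+p, K-1+p), cutpoints first
    log_likelihood: float
    null_log_likelihood: float
    n_used: int
    excluded_missing: int
    n_iter: int

    @property
    def beta_se(self) -> np.ndarray:
        k = len(self.cutpoints)
        return np.sqrt(np.diag(self.cov_params)[k:])

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.log_likelihood / self.null_log_likelihood

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Category probabilities per row of X; rows sum to 1."""
        eta = np.asarray(X, dtype=float) @ self.beta
        cum = special.expit(self.cutpoints[None, :] - eta[:, None])
        cum = np.concatenate(
            [np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1
        )
        return np.diff(cum, axis=1)


@dataclass(frozen=True)
class EffectEstimate:
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float


def build_design(cohort_or_frame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, int, tuple[str, ...]]:
    """Design matrix, inverted-category outcome vector, exclusion count.

    Accepts a Cohort or its to_frame() DataFrame.  Derived covariates:
    ``gcs_inverted = 15 - gcs``; ``pupil_abnormality = 1`` for unilateral
    or bilateral dilatation (normal = 0; untestable is missing).  Subjects
    missing any covariate or the outcome are dropped listwise.  The
    outcome is Y in {1, 2, 3} with 1 = good recovery (GOSE 7-8) and
    3 = severe disability (GOSE 1-4), so positive coefficients mean worse.
    """
    df = cohort_or_frame.to_frame() if isinstance(cohort_or_frame, Cohort) else cohort_or_frame.copy()
    df = df.reset_index(drop=True)
    work = pd.DataFrame(index=df.index)
    for name in spec.covariates:
        if name == "gcs_inverted":
            work[name] = 15.0 - pd.to_numeric(df["gcs"], errors="coerce")
        elif name == "pupil_abnormality":
            p = df["pupils"]
            work[name] = p.map(
                {"normal": 0.0, "unilateral": 1.0, "bilateral": 1.0}
            )
        else:
            work[name] = pd.to_numeric(df[name], errors="coerce")
    cat = pd.to_numeric(df["gose_category"], errors="coerce")
    work["_y"] = 4 - cat  # invert: category 3 (good) -> 1, category 1 (bad) -> 3
    kept = work.dropna()
    n_excluded = len(work) - len(kept)
    if len(kept) == 0:
        raise ValueError("no usable subjects after listwise deletion")
    n_params = len(spec.covariates) + 2
    if len(kept) < 10 * n_params:
        warnings.warn(
            f"only {len(kept)} usable subjects for {n_params} parameters",
            stacklevel=2,
        )
    X = kept[list(spec.covariates)].to_numpy(dtype=float)
    y = kept["_y"].to_numpy(dtype=int)
    return X, y, n_excluded, tuple(spec.covariates)


def _loglik_grad_hess(theta: np.ndarray, X: np.ndarray, y: np.ndarray, K: int):
    """Log-likelihood, gradient, Hessian of the proportional-odds model.

    theta = (alpha_1..alpha_{K-1}, beta); y in 1..K.
    """
    n, p = X.shape
    alpha = theta[: K - 1]
    beta = theta[K - 1 :]
    eta = X @ beta
    # z_k for each observation's upper and lower cut
    upper = np.where(y < K, alpha[np.minimum(y, K - 1) - 1] - eta, np.inf)
    lower = np.where(y > 1, alpha[np.maximum(y - 1, 1) - 1] - eta, -np.inf)
    A = special.expit(upper)
    B = special.expit(lower)
    P = np.clip(A - B, 1e-300, None)
    ll = float(np.log(P).sum())

    a = A * (1 - A)  # logistic pdf at upper (0 where infinite)
    b = B * (1 - B)
    ap = a * (1 - 2 * A)  # pdf derivative
    bp = b * (1 - 2 * B)
    u = a / P
    v = b / P

    g = np.zeros(K - 1 + p)
    H = np.zeros((K - 1 + p, K - 1 + p))
    has_up = y < K
    has_lo = y > 1
    iu = np.where(has_up, y - 1, 0)  # alpha index of upper cut
    il = np.where(has_lo, y - 2, 0)

    # gradient: cutpoints
    np.add.at(g, iu[has_up], u[has_up])
    np.add.at(g, il[has_lo], -v[has_lo])
    # gradient: beta
    g[K - 1 :] = -(X * (u - v)[:, None]).sum(axis=0)

    # Hessian blocks
    d_uu = ap / P - u * u  # d2/dalpha_up^2
    d_ll = -bp / P - v * v
    d_ul = u * v
    np.add.at(H, (iu[has_up], iu[has_up]), d_uu[has_up])
    np.add.at(H, (il[has_lo], il[has_lo]), d_ll[has_lo])
    both = has_up & has_lo
    np.add.at(H, (iu[both], il[both]), d_ul[both])
    np.add.at(H, (il[both], iu[both]), d_ul[both])
    # alpha-beta cross terms
    c_u = -ap / P + u * (u - v)  # coefficient of x for the upper cut
    c_l = bp / P - v * (u - v)
    for k in range(K - 1):
        m_u = has_up & (iu == k)
        m_l = has_lo & (il == k)
        row = np.zeros(p)
        if m_u.any():
            row += (X[m_u] * c_u[m_u, None]).sum(axis=0)
        if m_l.any():
            row += (X[m_l] * c_l[m_l, None]).sum(axis=0)
        H[k, K - 1 :] += row
        H[K - 1 :, k] += row
    # beta-beta block
    w = (ap - bp) / P - (u - v) ** 2
    H[K - 1 :, K - 1 :] = (X * w[:, None]).T @ X
    return ll, g, H


def _null_loglik(y: np.ndarray, K: int) -> float:
    n = len(y)
    counts = np.bincount(y, minlength=K + 1)[1:]
    nz = counts[counts > 0]
    return float((nz * np.log(nz / n)).sum())


def fit_proportional_odds(
    X: np.ndarray,
    y: np.ndarray,
    covariate_names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    excluded_missing: int = 0,
) -> OrdinalModelFit:
    """Maximum-likelihood fit by damped Newton iterations.

    Converged when the gradient max-norm drops below ``tol``.  Raises
    ConvergenceError (with the iteration trace) on failure and
    SeparationError naming the worst covariate when estimates diverge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    K = int(levels.max())
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("design matrix is rank deficient")
    names = covariate_names or tuple(f"x{i}" for i in range(p))

    # start at the intercepts-only optimum
    cum = np.cumsum(np.bincount(y, minlength=K + 1)[1:K]) / n
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    theta = np.concatenate([special.logit(cum), np.zeros(p)])
    ll, g, H = _loglik_grad_hess(theta, X, y, K)
    trace = [ll]
    for it in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H - 1e-6 * np.eye(len(g)), g)
        # damping: halve the step until the likelihood improves and the
        # cutpoints remain strictly increasing
        lam = 1.0
        for _ in range(60):
            cand = theta - lam * step
            if np.all(np.diff(cand[: K - 1]) > 0):
                ll_c, g_c, H_c = _loglik_grad_hess(cand, X, y, K)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                    theta, ll, g, H = cand, ll_c, g_c, H_c
                    break
            lam /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve the likelihood", trace)
        trace.append(ll)
        if np.max(np.abs(theta[K - 1 :])) > 50:
            worst = names[int(np.argmax(np.abs(theta[K - 1 :])))]
            raise SeparationError(f"complete separation suspected on covariate {worst!r}")
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    info = -H  # observed information
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return OrdinalModelFit(
        covariate_names=names,
        beta=theta[K - 1 :].copy(),
        cutpoints=theta[: K - 1].copy(),
        cov_params=cov,
        log_likelihood=ll,
        null_log_likelihood=_null_loglik(y, K),
        n_used=n,
        excluded_missing=excluded_missing,
        n_iter=it + 1,
    )


def fit_outcome_model(cohort_or_frame, spec: ModelSpec | str) -> OrdinalModelFit:
    """Convenience wrapper: build the design from a cohort and fit."""
    if isinstance(spec, str):
        spec = ModelSpec(MODEL_PRESETS[spec])
    X, y, n_excl, names = build_design(cohort_or_frame, spec)
    return fit_proportional_odds(X, y, names, excluded_missing=n_excl)


def effect_table(fit: OrdinalModelFit) -> list[EffectEstimate]:
    """Odds ratios, Wald 95% CIs and two-sided Wald p per covariate."""
    out = []
    for name, b, se in zip(fit.covariate_names, fit.beta, fit.beta_se):
        z = b / se if se > 0 else np.inf * np.sign(b)
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        out.append(
            EffectEstimate(
                covariate=name,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - _Z95 * se)),
                ci_high=float(np.exp(b + _Z95 * se)),
                wald_p=float(p),
            )
        )
    return out


def effect_frame(fit: OrdinalModelFit) -> pd.DataFrame:
    rows = [
        {
            "covariate": e.covariate,
            "OR": e.odds_ratio,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p": e.wald_p,
        }
        for e in effect_table(fit)
    ]
    df = pd.DataFrame(rows)
    df.attrs["mcfadden_r2"] = fit.mcfadden_r2
    return df


def mcfadden_r2(fit: OrdinalModelFit) -> float:
    """McFadden's pseudo R^2: 1 - ll / ll_null."""
    return fit.mcfadden_r2
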