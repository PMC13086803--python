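"""Synthetic 3D lesion-cohort generator.

Emulates the statistical structure of a moderate-severe TBI contusion
cohort: frontotemporal lesion predilection, heavy-tailed per-subject total
lesion volumes, clinical covariates (age, GCS, pupils, days to MRI, TAI
burden) and an 8-level GOSE outcome drawn from a proportional-odds model
whose linear predictor couples outcome to lesion volume and covariates —
and, optionally, to lesion *location* through a focal effect ``delta`` at a
designated focus region.  Lesion morphology (ellipsoidal kernel plus
smoothed noise, thresholded and clipped to the brain mask) is intentionally
simple: statistical structure, not anatomical realism, is the goal.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; draws are consumed in a fixed documented order (per subject:
covariates, lesion count, total volume, volume partition, hemorrhagic
fraction, per-lesion seed region / center / shape / noise, then the GOSE
uniform), so identical configs reproduce voxel-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

from .cohort_io import (
    HEMORRHAGIC,
    MERGED_REGIONS,
    REGION_NAMES,
    TOTAL,
    Cohort,
    LesionMask,
    RegionAtlas,
    SubjectRecord,
    VoxelGrid,
)

__all__ = [
    "SyntheticConfig",
    "VolumeUnattainableError",
    "EmptyRegionError",
    "GridTooSmallError",
    "make_default_atlas",
    "generate_cohort",
    "generate_null_cohort",
]


class VolumeUnattainableError(ValueError):
    """A drawn lesion volume exceeds what the brain mask can host."""


class EmptyRegionError(ValueError):
    """A region has positive seed weight but no atlas voxels."""


class GridTooSmallError(ValueError):
    """Grid too small to host all atlas regions (< 16 voxels per axis)."""


# Per-lesion seed-region probabilities, calibrated (with the default count
# distribution and lesion morphology on the default grid) so that
# subject-level presence approximates the clinical predilection pattern:
# frontal ~75%, temporal ~82%, parietal ~22%, occipital ~8%, cerebellum ~8%,
# deep ~5%, brainstem ~3%.
DEFAULT_REGION_WEIGHTS = {
    "frontal_L": 0.0500,
    "frontal_R": 0.0500,
    "temporal_L": 0.4100,
    "temporal_R": 0.4100,
    "parietal": 0.0383,
    "occipital": 0.0139,
    "cerebellum": 0.0139,
    "deep": 0.0087,
    "brainstem": 0.0052,
}

# Cumulative-logit cutpoints for GOSE levels 1..7 (P(GOSE <= k) on the
# logit scale at the reference covariate profile), calibrated so the
# marginal 3-category outcome split approximates 21% / 38% / 41%.
DEFAULT_CUTPOINTS = (-10.174, -9.823, -9.038, -8.405, -7.042, -5.763, -4.289)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions emulated.

    Outcome coefficients act on the worse-outcome scale of
    ``logit P(GOSE <= k) = alpha_k + eta`` with
    ``eta = beta_vol*dose(volume) + beta_age*age + beta_gcs*(15-gcs)
    + beta_tai*trondheim_grade + delta*[focus lesioned]``
    (dose is log1p or identity per ``volume_effect_scale``),
    so positive coefficients make low (bad) GOSE scores more likely.
    """

    n_subjects: int = 301
    grid: VoxelGrid | None = None
    atlas: RegionAtlas | None = None
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    #: lesions per subject = 1 + NegBinomial(r, p); default gives median 3, IQR 2-6
    lesion_count_nb: tuple[float, float] = (1.0, 0.24)
    #: log-normal (mu, sigma) of per-subject total volume in cm^3;
    #: default: median 13.76 cm^3, IQR ~ 2.8-39.5
    volume_lognormal: tuple[float, float] = (np.log(13.76), 1.954)
    #: totals are clipped to this fraction of the brain-mask volume
    max_total_fraction: float = 0.35
    #: symmetric Dirichlet concentration of the per-lesion volume split
    volume_partition_alpha: float = 1.0
    #: subject hemorrhagic fraction: 0 with prob p0, else Beta(a, b)
    hemorrhagic_zero_prob: float = 0.30
    hemorrhagic_beta: tuple[float, float] = (0.5, 4.0)
    #: covariates
    p_severe: float = 178 / 301
    p_male: float = 0.80
    age_lognormal: tuple[float, float] = (np.log(32.0), 0.63)
    age_range: tuple[float, float] = (8.0, 70.0)
    days_lognormal_severe: tuple[float, float] = (np.log(10.0), 0.95)
    days_lognormal_moderate: tuple[float, float] = (np.log(6.0), 1.14)
    missing_gcs_rate: float = 0.017
    missing_gose_rate: float = 0.07
    untestable_pupils_rate_severe: float = 0.011
    untestable_pupils_rate_moderate: float = 0.025
    tai_presence: tuple[float, float] = (0.87, 0.68)  # severe, moderate
    #: outcome model
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    #: dose scale of the volume effect: the linear predictor uses
    #: beta_vol * log1p(volume) ("log1p", default) or beta_vol * volume
    #: ("linear"); a saturating dose-response is the more physiological
    #: assumption for mass-lesion burden
    volume_effect_scale: str = "log1p"
    beta_vol: float = 0.55
    beta_age: float = 0.058
    beta_gcs: float = 0.336
    beta_tai: float = 0.231
    delta: float = 0.0
    focus_region: str | None = None
    #: skip voxel realization (covariates/volumes/outcomes only); requires delta == 0
    masks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array(list(self.region_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ValueError("region_weights must be non-negative and sum to 1")
        cp = np.asarray(self.cutpoints, dtype=float)
        if len(cp) != 7 or np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must be 7 strictly increasing values")
        if self.volume_lognormal[1] <= 0 or self.age_lognormal[1] <= 0:
            raise ValueError("variance parameters must be > 0")
        if self.delta != 0.0 and self.focus_region is None:
            raise ValueError("delta != 0 requires a focus_region")
        if self.delta != 0.0 and not self.masks:
            raise ValueError("a focal location effect requires mask generation")
        if self.volume_effect_scale not in ("log1p", "linear"):
            raise ValueError("volume_effect_scale must be 'log1p' or 'linear'")


def make_default_atlas(grid: VoxelGrid) -> RegionAtlas:
    """Deterministic coarse atlas: an ellipsoidal brain split into regions.

    The brain is the inscribed ellipsoid (92% of each half-extent); regions
    are carved by coordinate planes in normalized world coordinates
    (u: left->right, v: posterior->anterior, w: inferior->superior):
    a central deep core, a low central brainstem column, posterior-inferior
    cerebellum, posterior occipital cortex, lateral-inferior temporal
    lobes, anterior frontal lobes, and a parietal remainder.  Left/right
    follow world x, so mirroring the grid swaps lateralized labels.
    """
    if any(s < 16 for s in grid.shape):
        raise GridTooSmallError(f"grid {grid.shape} too small; need >= 16 voxels per axis")
    xyz = grid.world_coordinates()
    center = (xyz[0, 0, 0] + xyz[-1, -1, -1]) / 2.0
    half = np.abs(xyz[-1, -1, -1] - xyz[0, 0, 0]) / 2.0
    u, v, w = np.moveaxis((xyz - center) / (0.92 * half), -1, 0)
    r2 = u * u + v * v + w * w
    brain = r2 <= 1.0

    lab = np.zeros(grid.shape, dtype=np.int16)
    deep = r2 <= 0.30**2
    brainstem = (np.sqrt(u * u + (v + 0.15) ** 2) < 0.22) & (w < -0.30) & ~deep
    cerebellum = (v < -0.40) & (w < -0.30) & ~deep & ~brainstem
    occipital = (v < -0.55) & ~deep & ~brainstem & ~cerebellum
    temporal = (np.abs(u) > 0.40) & (w < 0.05) & (v <= 0.35) & ~(
        deep | brainstem | cerebellum | occipital
    )
    frontal = (v > 0.30) & ~(deep | brainstem | cerebellum | occipital | temporal)

    lab[brain] = REGION_NAMES["parietal"]
    lab[brain & deep] = REGION_NAMES["deep"]
    lab[brain & brainstem] = REGION_NAMES["brainstem"]
    lab[brain & cerebellum] = REGION_NAMES["cerebellum"]
    lab[brain & occipital] = REGION_NAMES["occipital"]
    lab[brain & temporal & (u < 0)] = REGION_NAMES["temporal_L"]
    lab[brain & temporal & (u >= 0)] = REGION_NAMES["temporal_R"]
    lab[brain & frontal & (u < 0)] = REGION_NAMES["frontal_L"]
    lab[brain & frontal & (u >= 0)] = REGION_NAMES["frontal_R"]

    atlas = RegionAtlas(grid=grid, labels=lab)
    sizes = atlas.region_sizes()
    empty = [name for name, n in sizes.items() if n == 0]
    if empty:
        raise GridTooSmallError(f"grid {grid.shape} leaves regions empty: {empty}")
    return atlas


def _realize_lesion(
    rng: np.random.Generator,
    grid: VoxelGrid,
    brain: np.ndarray,
    center: tuple[int, int, int],
    target_vox: int,
    noise_sigma_vox: float = 1.2,
    noise_amp: float = 0.25,
) -> np.ndarray:
    """Grow one connected lesion of ~target_vox voxels around ``center``.

    The lesion is the connected component (containing the center) of the
    thresholded sum of an anisotropic ellipsoidal kernel and smoothed
    Gaussian noise, restricted to the brain mask.  The threshold is chosen
    by quantile search so the component lands within 10% of the target.
    Returns an (m, 3) array of voxel indices.
    """
    vs = grid.voxel_size_mm
    radius_mm = (3.0 * target_vox * grid.voxel_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    aniso = np.exp(rng.normal(0.0, 0.25, size=3))
    aniso /= aniso.prod() ** (1.0 / 3.0)
    r_vox = np.maximum(radius_mm * aniso / vs, 0.6)

    shape = np.array(grid.shape)
    ctr = np.array(center)
    for expand in (2.4, 3.5, 10.0):  # widen the box if the brain edge truncates growth
        half = np.ceil(expand * r_vox + 3).astype(int)
        lo = np.maximum(ctr - half, 0)
        hi = np.minimum(ctr + half + 1, shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        bbrain = brain[box]
        if int(bbrain.sum()) >= target_vox or np.all(hi - lo == shape):
            break
    avail = int(bbrain.sum())
    if avail < target_vox:
        raise VolumeUnattainableError(
            f"lesion of {target_vox} voxels exceeds reachable brain volume ({avail})"
        )

    idx = np.indices(bbrain.shape).reshape(3, -1).T
    d = np.sqrt((((idx - (ctr - lo)) / r_vox) ** 2).sum(axis=1)).reshape(bbrain.shape)
    noise = ndimage.gaussian_filter(rng.standard_normal(bbrain.shape), noise_sigma_vox)
    sd = noise.std()
    if sd > 0:
        noise *= noise_amp / sd
    fld = (1.0 - d) + noise
    fld[~bbrain] = -np.inf

    vals = np.sort(fld[bbrain])[::-1]
    need = target_vox
    comp = None
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(40):
        thr = vals[min(need, avail) - 1]
        sel = fld >= thr
        labels, _ = ndimage.label(sel, structure=struct)
        comp = labels == labels[tuple(ctr - lo)]
        size = int(comp.sum())
        if size >= int(np.ceil(0.9 * target_vox)) or need >= avail:
            break
        need = min(int(need * 1.2) + 1, avail)
    if int(comp.sum()) > int(1.1 * target_vox) + 1:
        # trim lowest-field voxels back toward the target
        cf = fld[comp]
        keep_thr = np.sort(cf)[::-1][target_vox - 1]
        comp &= fld >= keep_thr
    where = np.argwhere(comp)
    return where + lo


_TRONDHEIM_P = {
    "severe": (0.10, 0.22, 0.28, 0.25, 0.15),
    "moderate": (0.25, 0.30, 0.25, 0.15, 0.05),
}
_STANDARD_FROM_TRONDHEIM = {1: 1, 2: 1, 3: 2, 4: 3, 5: 3}
_GCS_SEVERE = (np.arange(3, 9), (0.26, 0.08, 0.10, 0.14, 0.22, 0.20))
_GCS_MODERATE = (np.arange(9, 14), (0.08, 0.10, 0.22, 0.34, 0.26))
_PUPILS_P = {  # normal, unilateral, bilateral (untestable handled separately)
    "severe": (0.682, 0.256, 0.062),
    "moderate": (0.967, 0.025, 0.008),
}


def _draw_covariates(rng: np.random.Generator, cfg: SyntheticConfig) -> dict:
    severe = rng.random() < cfg.p_severe
    severity = "severe" if severe else "moderate"
    sex = "male" if rng.random() < cfg.p_male else "female"
    age = float(np.clip(rng.lognormal(*cfg.age_lognormal), *cfg.age_range))
    vals, probs = _GCS_SEVERE if severe else _GCS_MODERATE
    gcs = int(rng.choice(vals, p=np.asarray(probs) / np.sum(probs)))
    mu, sg = cfg.days_lognormal_severe if severe else cfg.days_lognormal_moderate
    days = float(np.clip(np.round(rng.lognormal(mu, sg)), 0, 42))
    unt = (
        cfg.untestable_pupils_rate_severe if severe else cfg.untestable_pupils_rate_moderate
    )
    if rng.random() < unt:
        pupils = None
    else:
        p = np.asarray(_PUPILS_P[severity])
        pupils = ["normal", "unilateral", "bilateral"][int(rng.choice(3, p=p / p.sum()))]
    tai_present = rng.random() < (cfg.tai_presence[0] if severe else cfg.tai_presence[1])
    if tai_present:
        p = np.asarray(_TRONDHEIM_P[severity])
        ttg = 1 + int(rng.choice(5, p=p / p.sum()))
        tai_vol = float(rng.lognormal(np.log(0.4 * ttg), 1.0))
    else:
        ttg = 1
        tai_vol = 0.0
    gcs_missing = rng.random() < cfg.missing_gcs_rate
    gose_missing = rng.random() < cfg.missing_gose_rate
    return dict(
        severity=severity, sex=sex, age=age, gcs=gcs, days_to_mri=days,
        pupils=pupils, tai_trondheim_grade=ttg,
        tai_standard_grade=_STANDARD_FROM_TRONDHEIM[ttg], tai_volume_cm3=tai_vol,
        gcs_missing=gcs_missing, gose_missing=gose_missing,
    )


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Draw a full synthetic cohort (masks, covariates, outcomes).

    Deterministic given ``cfg`` (including ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid if cfg.grid is not None else VoxelGrid.default()
    atlas = cfg.atlas if cfg.atlas is not None else make_default_atlas(grid)
    if not atlas.grid.matches(grid):
        raise ValueError("atlas grid differs from config grid")

    names = list(cfg.region_weights)
    weights = np.array([cfg.region_weights[n] for n in names], dtype=float)
    region_voxels = {}
    for n in names:
        if cfg.region_weights[n] > 0:
            vox = np.argwhere(atlas.region_mask(n))
            if len(vox) == 0:
                raise EmptyRegionError(f"region {n!r} has positive weight but no voxels")
            region_voxels[n] = vox
    brain = atlas.brain_mask
    brain_vox = int(brain.sum())
    vox_cm3 = grid.voxel_volume_mm3 / 1000.0
    cap_vox = int(cfg.max_total_fraction * brain_vox)

    focus = atlas.region_mask(cfg.focus_region) if cfg.focus_region else None
    cutpoints = np.asarray(cfg.cutpoints, dtype=float)
    r_nb, p_nb = cfg.lesion_count_nb

    subjects: list[SubjectRecord] = []
    for i in range(cfg.n_subjects):
        cov = _draw_covariates(rng, cfg)
        k_lesions = 1 + int(rng.negative_binomial(r_nb, p_nb))
        total_cm3 = float(rng.lognormal(*cfg.volume_lognormal))
        total_vox = int(np.clip(round(total_cm3 / vox_cm3), 1, cap_vox))
        frac = rng.dirichlet(np.full(k_lesions, cfg.volume_partition_alpha))
        per_vox = np.maximum(np.round(frac * total_vox).astype(int), 1)
        hem_frac = 0.0 if rng.random() < cfg.hemorrhagic_zero_prob else float(
            rng.beta(*cfg.hemorrhagic_beta)
        )

        masks: dict[str, LesionMask] = {}
        if cfg.masks:
            total_mask = np.zeros(grid.shape, dtype=bool)
            hem_mask = np.zeros(grid.shape, dtype=bool)
            for j in range(k_lesions):
                region = names[int(rng.choice(len(names), p=weights))]
                vox = region_voxels[region]
                center = tuple(vox[int(rng.integers(len(vox)))])
                lesion = _realize_lesion(rng, grid, brain, center, int(per_vox[j]))
                total_mask[tuple(lesion.T)] = True
                if hem_frac > 0:
                    n_hem = int(round(hem_frac * len(lesion)))
                    if n_hem > 0:
                        # hemorrhagic core: the voxels nearest the lesion center
                        d = np.linalg.norm((lesion - np.array(center)) * grid.voxel_size_mm, axis=1)
                        core = lesion[np.argsort(d, kind="stable")[:n_hem]]
                        hem_mask[tuple(core.T)] = True
            masks[TOTAL] = LesionMask(grid, TOTAL, total_mask)
            masks[HEMORRHAGIC] = LesionMask(grid, HEMORRHAGIC, hem_mask)
            vol_total = masks[TOTAL].volume_cm3
            vol_hem = masks[HEMORRHAGIC].volume_cm3
            focal = bool(np.any(total_mask & focus)) if focus is not None else False
        else:
            vol_total = total_vox * vox_cm3
            vol_hem = hem_frac * vol_total
            focal = False

        vol_dose = np.log1p(vol_total) if cfg.volume_effect_scale == "log1p" else vol_total
        eta = (
            cfg.beta_vol * vol_dose
            + cfg.beta_age * cov["age"]
            + cfg.beta_gcs * (15 - cov["gcs"])
            + cfg.beta_tai * cov["tai_trondheim_grade"]
            + (cfg.delta if focal else 0.0)
        )
        cum = _expit(cutpoints + eta)
        gose = 1 + int(np.sum(rng.random() > cum))

        rec = SubjectRecord(
            id=f"S{i + 1:04d}",
            severity=cov["severity"],
            age=cov["age"],
            sex=cov["sex"],
            gcs=None if cov["gcs_missing"] else cov["gcs"],
            pupils=cov["pupils"],
            days_to_mri=cov["days_to_mri"],
            gose=None if cov["gose_missing"] else gose,
            tai_trondheim_grade=cov["tai_trondheim_grade"],
            tai_standard_grade=cov["tai_standard_grade"],
            tai_volume_cm3=cov["tai_volume_cm3"],
            masks=masks,
            total_volume_cm3=vol_total,
            hemorrhagic_volume_cm3=vol_hem,
        )
        if cfg.masks:
            from .cohort_io import compute_region_presence

            rec.region_presence = compute_region_presence(masks[TOTAL], atlas)
        subjects.append(rec)
    return Cohort(grid, subjects)


def generate_null_cohort(cfg: SyntheticConfig) -> Cohort:
    """As generate_cohort, but outcomes are independent of all lesion
    quantities (beta_vol = delta = 0); covariate effects remain."""
    return generate_cohort(replace(cfg, beta_vol=0.0, delta=0.0, focus_region=None))
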