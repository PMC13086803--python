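"""Lesion frequency distribution maps.

A frequency map holds, for a stratum of subjects, the per-voxel count of
subjects whose lesion covers that voxel and the corresponding relative
frequency (count / stratum size).  Maps can be stratified by injury
severity or outcome category, projected for display, and written as paired
NIfTI volumes (integer counts, float frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import nibabel as nib
import numpy as np

from .cohort_io import TOTAL, Cohort, SubjectRecord, VoxelGrid

__all__ = [
    "FrequencyMap",
    "EmptyStratumError",
    "overlap_counts",
    "stratified_maps",
    "max_intensity_projection",
    "display_scaled",
    "write_frequency_map",
]


class EmptyStratumError(ValueError):
    """No subjects selected for a frequency map."""


@dataclass
class FrequencyMap:
    grid: VoxelGrid
    counts: np.ndarray
    n_subjects: int
    stratum_label: str
    component: str

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != self.grid.shape:
            raise ValueError("counts shape differs from grid shape")
        if self.n_subjects < 1:
            raise EmptyStratumError(f"stratum {self.stratum_label!r} has no subjects")
        if c.min() < 0 or c.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")
        self.counts = c.astype(np.int32)

    @property
    def relative_frequency(self) -> np.ndarray:
        return self.counts / float(self.n_subjects)


def overlap_counts(
    cohort: Cohort,
    component: str = TOTAL,
    subject_filter: Callable[[SubjectRecord], bool] | None = None,
    stratum_label: str = "all",
) -> FrequencyMap:
    """Per-voxel count of selected subjects whose mask covers each voxel."""
    subs = [s for s in cohort.subjects if subject_filter is None or subject_filter(s)]
    if not subs:
        raise EmptyStratumError(f"stratum {stratum_label!r} selects no subjects")
    counts = np.zeros(cohort.grid.shape, dtype=np.int32)
    for s in subs:
        if component not in s.masks:
            raise KeyError(f"{s.id}: missing {component!r} mask")
        counts += s.masks[component].data
    return FrequencyMap(cohort.grid, counts, len(subs), stratum_label, component)


_GROUPERS = {
    "none": lambda s: "all",
    "severity": lambda s: s.severity,
    "gose_category": lambda s: s.gose_category,
}


def stratified_maps(
    cohort: Cohort, component: str = TOTAL, by: str = "none"
) -> dict[str, FrequencyMap]:
    """One frequency map per level of the grouping variable.

    Subjects missing the grouping variable are excluded (their count is
    retrievable as len(cohort) minus the sum of stratum sizes).
    """
    if by not in _GROUPERS:
        raise KeyError(f"unknown grouping key {by!r}; use one of {sorted(_GROUPERS)}")
    keyf = _GROUPERS[by]
    levels = sorted({keyf(s) for s in cohort.subjects if keyf(s) is not None}, key=str)
    out = {}
    for level in levels:
        label = "all" if by == "none" else f"{by}={level}"
        out[str(level)] = overlap_counts(
            cohort, component, lambda s, lv=level: keyf(s) == lv, label
        )
    return out


def max_intensity_projection(fmap: FrequencyMap, axis: int) -> np.ndarray:
    """2D maximum of relative frequency along one collapsed axis."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    return fmap.relative_frequency.max(axis=axis)


def display_scaled(
    fmap: FrequencyMap, upper: float = 0.20
) -> tuple[np.ndarray, dict]:
    """Display values in [0, 1] for the rendered overlay.

    Relative frequencies are clipped to [1/n, upper] then mapped affinely
    to [0, 1]; the lower anchor is one subject per voxel and the default
    upper anchor 20% is the conventional hot end of the colour scale.
    Count-0 voxels carry NaN (transparent / absent from the overlay).
    """
    lower = 1.0 / fmap.n_subjects
    if upper <= lower:
        raise ValueError("upper bound must exceed one subject's relative frequency")
    rf = fmap.relative_frequency
    disp = (np.clip(rf, lower, upper) - lower) / (upper - lower)
    disp[fmap.counts == 0] = np.nan
    cmap = {"colormap": "jet", "vmin": lower, "vmax": upper}
    return disp, cmap


def write_frequency_map(fmap: FrequencyMap, out_dir: str | Path) -> tuple[Path, Path]:
    """Write paired NIfTI volumes: lossless integer counts and float32
    relative frequencies."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = fmap.stratum_label.replace("=", "_")
    cpath = out_dir / f"counts_{fmap.component}_{stem}.nii.gz"
    fpath = out_dir / f"frequency_{fmap.component}_{stem}.nii.gz"
    nib.save(nib.Nifti1Image(fmap.counts.astype(np.int32), fmap.grid.affine), str(cpath))
    nib.save(
        nib.Nifti1Image(fmap.relative_frequency.astype(np.float32), fmap.grid.affine),
        str(fpath),
    )
    return cpath, fpath
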