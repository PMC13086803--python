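"""Shared raster geometry, lesion masks and the cohort data model.

All analyses in this package operate on binary lesion segmentations that
have already been registered to a common template grid (e.g. MNI space).
This module defines that grid, the per-subject lesion masks and clinical
records, and NIfTI/manifest I/O.  No resampling is performed: a mask whose
geometry does not match the cohort grid is rejected, never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TOTAL",
    "HEMORRHAGIC",
    "NON_HEMORRHAGIC",
    "COMPONENTS",
    "VoxelGrid",
    "LesionMask",
    "SubjectRecord",
    "Cohort",
    "RegionAtlas",
    "REGION_NAMES",
    "MERGED_REGIONS",
    "GridMismatchError",
    "DuplicateSubjectError",
    "SeverityGCSError",
    "MaskReadError",
    "gose_to_category",
    "read_mask",
    "write_mask",
    "mask_volume_cm3",
    "load_cohort",
    "save_cohort",
    "tabulate_region_presence",
]

TOTAL = "total"
HEMORRHAGIC = "hemorrhagic"
NON_HEMORRHAGIC = "non_hemorrhagic"
COMPONENTS = (TOTAL, HEMORRHAGIC, NON_HEMORRHAGIC)

#: Atlas label codes.  0 is reserved for outside_brain.
REGION_NAMES = {
    "frontal_L": 1,
    "frontal_R": 2,
    "temporal_L": 3,
    "temporal_R": 4,
    "parietal": 5,
    "occipital": 6,
    "cerebellum": 7,
    "deep": 8,
    "brainstem": 9,
}

#: Subject-level presence is reported on merged (bilateral) regions, the
#: granularity at which clinical lesion-location tables are tabulated.
MERGED_REGIONS = {
    "frontal": ("frontal_L", "frontal_R"),
    "temporal": ("temporal_L", "temporal_R"),
    "parietal": ("parietal",),
    "occipital": ("occipital",),
    "cerebellum": ("cerebellum",),
    "deep": ("deep",),
    "brainstem": ("brainstem",),
}


class GridMismatchError(ValueError):
    """Raster geometry does not match the cohort grid."""


class DuplicateSubjectError(ValueError):
    """Two manifest rows share a subject id."""


class SeverityGCSError(ValueError):
    """Stated severity contradicts the GCS score."""


class MaskReadError(ValueError):
    """A mask file could not be ingested."""


def gose_to_category(gose: float | None) -> int | None:
    """Map a GOSE score (1-8) to the 3-level outcome category.

    1: GOSE 1-4 (severe disability / death), 2: GOSE 5-6 (moderate
    disability), 3: GOSE 7-8 (good recovery).  Returns None for missing.
    """
    if gose is None or (isinstance(gose, float) and np.isnan(gose)):
        return None
    g = int(gose)
    if not 1 <= g <= 8:
        raise ValueError(f"GOSE score out of range 1-8: {gose}")
    if g <= 4:
        return 1
    if g <= 6:
        return 2
    return 3


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D raster geometry: shape plus a 4x4 index->world (mm) affine.

    The affine follows the RAS+ convention; voxel sizes are the column
    norms of its 3x3 block.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive extents, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @classmethod
    def default(
        cls,
        shape: tuple[int, int, int] = (24, 28, 24),
        voxel_size_mm: float | Sequence[float] = 3.0,
    ) -> "VoxelGrid":
        """Centered RAS+ grid; the desk-scale default is 24x28x24 at 3 mm."""
        vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
        return cls(tuple(shape), aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VoxelGrid", tol_mm: float = 1e-3) -> bool:
        return self.shape == other.shape and bool(
            np.all(np.abs(self.affine - other.affine) <= tol_mm)
        )


@dataclass
class LesionMask:
    """A binary lesion raster for one subject and one component label."""

    grid: VoxelGrid
    component: str
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        arr = np.asarray(self.data)
        if arr.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {arr.shape} != grid shape {self.grid.shape}"
            )
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be exactly 0 or 1")
            arr = arr.astype(bool)
        self.data = arr

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


def mask_volume_cm3(mask: LesionMask) -> float:
    """Lesion volume in cm^3: voxel count x voxel volume (mm^3) / 1000."""
    return mask.volume_cm3


def read_mask(path: str | Path, grid: VoxelGrid, component: str = TOTAL) -> LesionMask:
    """Read a NIfTI mask, check geometry against ``grid`` and binarize.

    Float rasters are binarized with the rule value > 0.5 -> 1, tolerating
    interpolation dust from upstream registration.  Shape or affine
    mismatch beyond 1e-3 mm, and non-finite voxels, are rejected.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if tuple(data.shape) != grid.shape:
        raise MaskReadError(
            f"{path}: shape {tuple(data.shape)} does not match grid {grid.shape}"
        )
    if np.max(np.abs(img.affine - grid.affine)) > 1e-3:
        raise MaskReadError(f"{path}: affine differs from the cohort grid by >1e-3 mm")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise MaskReadError(f"{path}: non-finite voxel values")
    return LesionMask(grid=grid, component=component, data=data > 0.5)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


@dataclass
class SubjectRecord:
    """Clinical covariates, outcome and lesion masks for one subject."""

    id: str
    severity: str  # moderate | severe
    age: float
    sex: str  # male | female
    gcs: int | None = None
    pupils: str | None = None  # normal | unilateral | bilateral | None
    days_to_mri: float | None = None
    gose: int | None = None
    tai_trondheim_grade: int | None = None
    tai_standard_grade: int | None = None
    tai_volume_cm3: float | None = None
    masks: dict[str, LesionMask] = field(default_factory=dict)
    total_volume_cm3: float = 0.0
    hemorrhagic_volume_cm3: float = 0.0
    region_presence: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.severity not in ("moderate", "severe"):
            raise ValueError(f"{self.id}: severity must be moderate|severe")
        if self.gcs is not None:
            g = int(self.gcs)
            if g > 13 or g < 3:
                raise SeverityGCSError(
                    f"{self.id}: GCS {g} outside the moderate-severe range 3-13"
                )
            implied = "severe" if g <= 8 else "moderate"
            if implied != self.severity:
                raise SeverityGCSError(
                    f"{self.id}: severity {self.severity!r} contradicts GCS {g}"
                )
        if self.gose is not None and not 1 <= int(self.gose) <= 8:
            raise ValueError(f"{self.id}: GOSE {self.gose} out of range")
        if TOTAL in self.masks and not self.masks:
            pass
        if self.masks:
            if TOTAL in self.masks:
                self.total_volume_cm3 = self.masks[TOTAL].volume_cm3
            if HEMORRHAGIC in self.masks:
                self.hemorrhagic_volume_cm3 = self.masks[HEMORRHAGIC].volume_cm3
        if self.total_volume_cm3 + 1e-9 < self.hemorrhagic_volume_cm3:
            raise ValueError(
                f"{self.id}: hemorrhagic volume exceeds total volume"
            )

    @property
    def gose_category(self) -> int | None:
        return gose_to_category(self.gose)

    def validate_component_inclusion(self) -> bool:
        """Check hemorrhagic/non-hemorrhagic 1-voxels are a subset of total.

        Components were segmented independently upstream, so a violation is
        reported as a warning by the loader rather than a hard failure.
        """
        if TOTAL not in self.masks:
            return True
        total = self.masks[TOTAL].data
        for comp in (HEMORRHAGIC, NON_HEMORRHAGIC):
            if comp in self.masks and np.any(self.masks[comp].data & ~total):
                return False
        return True


@dataclass
class Cohort:
    """An ordered collection of subjects sharing one voxel grid."""

    grid: VoxelGrid
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateSubjectError(f"duplicate subject ids: {dup}")
        for s in self.subjects:
            for m in s.masks.values():
                if not m.grid.matches(self.grid):
                    raise GridMismatchError(f"{s.id}: mask grid differs from cohort grid")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subset(self, predicate) -> "Cohort":
        return Cohort(self.grid, [s for s in self.subjects if predicate(s)])

    def lesion_matrix(self, component: str = TOTAL) -> np.ndarray:
        """Stack every subject's mask into an (n_subjects, n_voxels) bool array."""
        rows = []
        for s in self.subjects:
            if component not in s.masks:
                raise KeyError(f"{s.id}: missing {component!r} mask")
            rows.append(s.masks[component].data.reshape(-1))
        return np.array(rows, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Clinical covariates and derived measures as a DataFrame."""
        rows = []
        for s in self.subjects:
            row = {
                "id": s.id,
                "severity": s.severity,
                "age": s.age,
                "sex": s.sex,
                "gcs": s.gcs,
                "pupils": s.pupils,
                "days_to_mri": s.days_to_mri,
                "gose": s.gose,
                "gose_category": s.gose_category,
                "tai_trondheim_grade": s.tai_trondheim_grade,
                "tai_standard_grade": s.tai_standard_grade,
                "tai_volume_cm3": s.tai_volume_cm3,
                "total_volume_cm3": s.total_volume_cm3,
                "hemorrhagic_volume_cm3": s.hemorrhagic_volume_cm3,
            }
            if s.region_presence:
                for r, v in s.region_presence.items():
                    row[f"region_{r}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RegionAtlas:
    """Coarse anatomical parcellation on the cohort grid.

    ``labels`` holds integer region codes (see REGION_NAMES); 0 marks
    voxels outside the brain.  The brain mask must be non-empty.
    """

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise GridMismatchError("atlas labels shape differs from grid shape")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int16)
        if not np.any(lab > 0):
            raise ValueError("atlas brain mask is empty")
        bad = set(np.unique(lab)) - ({0} | set(REGION_NAMES.values()))
        if bad:
            raise ValueError(f"unknown atlas label codes: {sorted(bad)}")
        self.labels = lab

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, name: str) -> np.ndarray:
        if name in REGION_NAMES:
            return self.labels == REGION_NAMES[name]
        if name in MERGED_REGIONS:
            codes = [REGION_NAMES[r] for r in MERGED_REGIONS[name]]
            return np.isin(self.labels, codes)
        raise KeyError(f"unknown region {name!r}")

    def region_sizes(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for name, code in REGION_NAMES.items()}


def compute_region_presence(mask: LesionMask, atlas: RegionAtlas) -> dict[str, bool]:
    """Subject-level lesion presence per merged region (any intersecting voxel)."""
    if not atlas.grid.matches(mask.grid):
        raise GridMismatchError("atlas grid differs from mask grid")
    hit = np.unique(atlas.labels[mask.data])
    out = {}
    for merged, parts in MERGED_REGIONS.items():
        out[merged] = bool(np.any(np.isin([REGION_NAMES[p] for p in parts], hit)))
    return out


MANIFEST_COLUMNS = [
    "id", "severity", "age", "sex", "gcs", "pupils", "days_to_mri", "gose",
    "tai_trondheim_grade", "tai_standard_grade", "tai_volume_cm3",
    "mask_total", "mask_hemorrhagic",
]

_INT_FIELDS = ("gcs", "gose", "tai_trondheim_grade", "tai_standard_grade")


def _cell(row: Mapping, key: str):
    v = row.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def load_cohort(
    manifest: str | Path,
    mask_dir: str | Path | None,
    grid: VoxelGrid,
    atlas: RegionAtlas | None = None,
) -> Cohort:
    """Read a cohort from a manifest table plus per-subject NIfTI masks.

    The manifest is UTF-8 CSV or TSV (by extension) with a header row;
    missing clinical values are empty cells.  ``mask_total`` /
    ``mask_hemorrhagic`` columns name mask files relative to ``mask_dir``;
    hemorrhagic is optional.  Subjects with missing GOSE are retained.
    """
    manifest = Path(manifest)
    sep = "\t" if manifest.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(manifest, sep=sep, dtype={"id": str})
    missing_cols = set(MANIFEST_COLUMNS[:-2]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {sorted(missing_cols)}")
    seen: set[str] = set()
    subjects: list[SubjectRecord] = []
    for _, row in df.iterrows():
        sid = str(row["id"])
        if sid in seen:
            raise DuplicateSubjectError(f"duplicate subject id {sid!r} in manifest")
        seen.add(sid)
        masks: dict[str, LesionMask] = {}
        if mask_dir is not None:
            for comp, col in ((TOTAL, "mask_total"), (HEMORRHAGIC, "mask_hemorrhagic")):
                fname = _cell(row, col)
                if fname is not None:
                    masks[comp] = read_mask(Path(mask_dir) / str(fname), grid, comp)
        kwargs = {}
        for f in ("age", "days_to_mri", "tai_volume_cm3"):
            v = _cell(row, f)
            kwargs[f] = float(v) if v is not None else None
        for f in _INT_FIELDS:
            v = _cell(row, f)
            kwargs[f] = int(float(v)) if v is not None else None
        rec = SubjectRecord(
            id=sid,
            severity=str(row["severity"]),
            sex=str(row["sex"]),
            pupils=_cell(row, "pupils"),
            masks=masks,
            **kwargs,
        )
        if not rec.validate_component_inclusion():
            warnings.warn(
                f"{sid}: hemorrhagic component extends outside the total mask "
                "(components segmented independently)",
                stacklevel=2,
            )
        if atlas is not None and TOTAL in masks:
            rec.region_presence = compute_region_presence(masks[TOTAL], atlas)
        subjects.append(rec)
    return Cohort(grid, subjects)


def save_cohort(cohort: Cohort, out_dir: str | Path, masks: bool = True) -> Path:
    """Write a cohort as manifest.tsv plus one NIfTI per subject-component."""
    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    rows = []
    if masks:
        mask_dir.mkdir(parents=True, exist_ok=True)
    else:
        out_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        row = {
            "id": s.id, "severity": s.severity, "age": s.age, "sex": s.sex,
            "gcs": s.gcs, "pupils": s.pupils, "days_to_mri": s.days_to_mri,
            "gose": s.gose, "tai_trondheim_grade": s.tai_trondheim_grade,
            "tai_standard_grade": s.tai_standard_grade,
            "tai_volume_cm3": s.tai_volume_cm3,
            # derived measures, so the manifest alone supports tabular analyses
            "total_volume_cm3": s.total_volume_cm3,
            "hemorrhagic_volume_cm3": s.hemorrhagic_volume_cm3,
            "gose_category": s.gose_category,
            "mask_total": None, "mask_hemorrhagic": None,
        }
        if masks:
            for comp, col in ((TOTAL, "mask_total"), (HEMORRHAGIC, "mask_hemorrhagic")):
                if comp in s.masks:
                    fname = f"{s.id}_{comp}.nii.gz"
                    write_mask(s.masks[comp], mask_dir / fname)
                    row[col] = fname
        rows.append(row)
    path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def tabulate_region_presence(cohort: Cohort, atlas: RegionAtlas) -> pd.DataFrame:
    """Per-region subject counts and percentages, overall and by severity.

    A subject counts for a region iff their total lesion mask intersects
    any voxel of that (merged bilateral) region.
    """
    if not atlas.grid.matches(cohort.grid):
        raise GridMismatchError("atlas grid differs from cohort grid")
    presence = {}
    for s in cohort.subjects:
        if s.region_presence is not None:
            presence[s.id] = s.region_presence
        elif TOTAL in s.masks:
            presence[s.id] = compute_region_presence(s.masks[TOTAL], atlas)
        else:
            raise KeyError(f"{s.id}: no total mask and no precomputed region presence")
    strata = {
        "all": [s for s in cohort.subjects],
        "severe": [s for s in cohort.subjects if s.severity == "severe"],
        "moderate": [s for s in cohort.subjects if s.severity == "moderate"],
    }
    rows = []
    for region in MERGED_REGIONS:
        row: dict[str, object] = {"region": region}
        for name, subs in strata.items():
            n = len(subs)
            k = sum(presence[s.id][region] for s in subs)
            row[f"n_{name}"] = k
            row[f"pct_{name}"] = 100.0 * k / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
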