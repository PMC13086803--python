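"""End-to-end pipeline: simulate -> frequency maps -> VLSM -> outcome
models -> cohort statistics, with config, logging and provenance.

A run is driven by a YAML config (or an equivalent dict).  Outputs land in
``out_dir`` together with ``run_manifest.json`` recording the seed, the
fully-resolved config, per-stage status and a SHA-256 hash of every file
written, so any output is traceable to its run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    TOTAL,
    Cohort,
    VoxelGrid,
    load_cohort,
    save_cohort,
    tabulate_region_presence,
)
from .cohort_stats import contingency_test, jonckheere_terpstra, mann_whitney_u
from .frequency_maps import stratified_maps, write_frequency_map
from .outcome_models import MODEL_PRESETS, effect_frame, fit_outcome_model
from .synthetic import SyntheticConfig, generate_cohort, make_default_atlas
from .vlsm import VLSMParams, run_vlsm

__all__ = ["ConfigError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "freqmap", "vlsm", "fit-outcome", "stats")


class ConfigError(ValueError):
    """A config schema violation, reported with its field path."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    known = {"seed", "out_dir", "manifest", "mask_dir", "stages",
             "synthetic", "freqmap", "vlsm", "models", "grid"}
    for key in cfg:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
    stages = cfg.get("stages", list(_STAGES))
    for s in stages:
        if s not in _STAGES:
            raise ConfigError(f"stages: unknown stage {s!r}")
    if "synthetic" in cfg and not isinstance(cfg["synthetic"], dict):
        raise ConfigError("synthetic: must be a mapping")
    if "synthetic" in cfg:
        valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
        for k in cfg["synthetic"]:
            if k not in valid:
                raise ConfigError(f"synthetic.{k}: unknown field")
    if "vlsm" in cfg:
        valid = {f.name for f in dataclasses.fields(VLSMParams)}
        for k in cfg.get("vlsm") or {}:
            if k not in valid:
                raise ConfigError(f"vlsm.{k}: unknown field")
    for m in cfg.get("models", []):
        if m not in MODEL_PRESETS:
            raise ConfigError(f"models: unknown preset {m!r}")
    if "synthetic" not in cfg and "simulate" in stages:
        raise ConfigError("stages include 'simulate' but no synthetic block given")
    if "synthetic" not in cfg and "manifest" not in cfg:
        raise ConfigError("either a synthetic block or manifest/mask_dir is required")
    if "manifest" in cfg and "mask_dir" not in cfg:
        raise ConfigError("mask_dir: required when manifest is given")


def _grid_from_config(cfg: dict) -> VoxelGrid:
    g = cfg.get("grid") or {}
    return VoxelGrid.default(
        tuple(g.get("shape", (24, 28, 24))), g.get("voxel_size_mm", 3.0)
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _stats_tables(cohort: Cohort, atlas) -> pd.DataFrame:
    """Baseline-table statistics mirroring the clinical report layout."""
    df = cohort.to_frame()
    rows = []
    sev = df[df.severity == "severe"]
    mod = df[df.severity == "moderate"]
    for var in ("total_volume_cm3", "hemorrhagic_volume_cm3", "age", "days_to_mri"):
        if len(sev) and len(mod):
            r = mann_whitney_u(sev[var].dropna(), mod[var].dropna())
            rows.append({"analysis": f"{var} by severity", "test": "mann-whitney",
                         "statistic": r.u, "p": r.p_two_sided})
    with_cat = df.dropna(subset=["gose_category"])
    cats = sorted(with_cat.gose_category.unique())
    if len(cats) >= 3:
        for var in ("total_volume_cm3", "tai_trondheim_grade"):
            groups = [with_cat.loc[with_cat.gose_category == c, var].dropna() for c in cats]
            # worst category first: trend of decreasing volume with recovery
            r = jonckheere_terpstra(groups)
            rows.append({"analysis": f"trend {var} by gose_category", "test": "jonckheere-terpstra",
                         "statistic": r.jt_statistic, "p": r.p_two_sided})
    if atlas is not None:
        pres = tabulate_region_presence(cohort, atlas)
        n_sev = int((df.severity == "severe").sum())
        n_mod = int((df.severity == "moderate").sum())
        for _, row in pres.iterrows():
            a, b = int(row.n_severe), int(row.n_moderate)
            if 0 < a + b and n_sev and n_mod:
                tab = [[a, n_sev - a], [b, n_mod - b]]
                try:
                    r = contingency_test(tab)
                except ValueError:
                    continue
                rows.append({"analysis": f"region {row.region} by severity",
                             "test": r.test_used, "statistic": r.statistic,
                             "p": r.p_two_sided})
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Any stage failure propagates after the run manifest is written, leaving
    an intact partial directory.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    if "out_dir" not in cfg:
        raise ConfigError("out_dir: required")
    _validate(cfg)
    if "manifest" in cfg:
        mask_dir = Path(cfg["mask_dir"])
        if not mask_dir.is_dir():
            raise ConfigError(f"mask_dir: {mask_dir} is not a directory")

    run_dir = Path(cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("lesionmap").addHandler(handler)

    stages = cfg.get("stages", list(_STAGES))
    manifest: dict = {
        "package": "lesionmap", "version": __version__, "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()}, "stages": {}, "files": {},
    }
    grid = _grid_from_config(cfg)
    atlas = make_default_atlas(grid)
    cohort: Cohort | None = None
    try:
        if "simulate" in stages:
            syn = dict(cfg.get("synthetic") or {})
            syn.setdefault("seed", cfg["seed"])
            scfg = SyntheticConfig(grid=grid, atlas=atlas, **syn)
            cohort = generate_cohort(scfg)
            save_cohort(cohort, run_dir / "cohort")
            with open(run_dir / "cohort" / "resolved_config.json", "w") as fh:
                json.dump({k: _jsonable(v) for k, v in dataclasses.asdict(scfg).items()
                           if k not in ("grid", "atlas")}, fh, indent=2)
            manifest["stages"]["simulate"] = {"status": "ok", "n_subjects": len(cohort)}
        if cohort is None:
            cohort = load_cohort(cfg["manifest"], cfg["mask_dir"], grid, atlas)

        if "freqmap" in stages:
            fdir = run_dir / "freqmaps"
            opts = cfg.get("freqmap") or {}
            for by in opts.get("by", ["none", "severity", "gose_category"]):
                for _, fmap in stratified_maps(cohort, opts.get("component", TOTAL), by).items():
                    write_frequency_map(fmap, fdir)
            manifest["stages"]["freqmap"] = {"status": "ok"}

        if "vlsm" in stages:
            vp = VLSMParams(**{"seed": cfg["seed"], **(cfg.get("vlsm") or {})})
            res = run_vlsm(cohort, vp)
            _write_vlsm(res, cohort, run_dir / "vlsm")
            manifest["stages"]["vlsm"] = {
                "status": "ok", "n_tested": res.n_tested,
                "n_significant": res.n_significant,
                "critical_t": res.critical_t if np.isfinite(res.critical_t) else None,
            }

        if "fit-outcome" in stages:
            mdir = run_dir / "models"
            mdir.mkdir(exist_ok=True)
            for name in cfg.get("models", list(MODEL_PRESETS)):
                fit = fit_outcome_model(cohort, name)
                frame = effect_frame(fit)
                frame["mcfadden_r2"] = fit.mcfadden_r2
                frame.to_csv(mdir / f"{name}.tsv", sep="\t", index=False)
            manifest["stages"]["fit-outcome"] = {"status": "ok"}

        if "stats" in stages:
            _stats_tables(cohort, atlas).to_csv(run_dir / "stats.tsv", sep="\t", index=False)
            manifest["stages"]["stats"] = {"status": "ok"}
    except Exception as exc:
        failed = next((s for s in stages if s not in manifest["stages"]), "?")
        manifest["stages"][failed] = {"status": "failed", "error": str(exc)}
        _finalize(manifest, run_dir, handler)
        raise
    _finalize(manifest, run_dir, handler)
    return run_dir


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    return v


def _write_vlsm(res, cohort: Cohort, out_dir: Path) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    aff = cohort.grid.affine
    nib.save(nib.Nifti1Image(np.nan_to_num(res.t_map).astype(np.float32), aff),
             str(out_dir / "t_map.nii.gz"))
    nib.save(nib.Nifti1Image(res.significant_mask.astype(np.uint8), aff),
             str(out_dir / "significant.nii.gz"))
    nib.save(nib.Nifti1Image(np.nan_to_num(res.fwe_p_map, nan=1.0).astype(np.float32), aff),
             str(out_dir / "fwe_p.nii.gz"))
    finite_p = res.fwe_p_map[np.isfinite(res.fwe_p_map)]
    pd.DataFrame([{
        "n_subjects": res.n_subjects,
        "excluded_missing_outcome": res.n_excluded_missing_outcome,
        "n_tested_voxels": res.n_tested,
        "critical_t": res.critical_t,
        "n_significant": res.n_significant,
        "min_fwe_p": float(finite_p.min()) if finite_p.size else np.nan,
    }]).to_csv(out_dir / "summary.tsv", sep="\t", index=False)


def _finalize(manifest: dict, run_dir: Path, handler: logging.Handler) -> None:
    logging.getLogger("lesionmap").removeHandler(handler)
    handler.close()
    for path in sorted(run_dir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest["files"][str(path.relative_to(run_dir))] = _sha256(path)
    with open(run_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
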