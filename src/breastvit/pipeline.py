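"""End-to-end simulation pipeline and preview projection.

``run_pipeline`` wires the stages together — cohort → copula fit → density
calibration → per-woman timeline → per-age phantoms (+ optional lesion
insertion) — from a single serializable configuration, and writes a manifest
recording every seed and achieved metric so an archived config reproduces a
run bit-exactly.

``project_raysum`` is deliberately simple plumbing: an orthographic sum of
glandular weights along one axis, scaled to 8-bit grayscale.  It gives a
quick visual check of a phantom; physically realistic projection, noise and
reconstruction belong to dedicated external imaging toolchains.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import insertion as ins_mod
from .lesion import GrowthModel, generate_lesion
from .phantom import (
    Phantom,
    PhantomSpec,
    build_phantom,
    compute_vbd,
    save_phantom,
)
from .population import fit_copula
from .temporal import build_timeline
from .texture import DensityCalibration, calibrate_density

log = logging.getLogger("breastvit")

__all__ = ["RunConfig", "project_raysum", "run_pipeline"]

_AXES = {"x": 0, "y": 1, "z": 2}


def project_raysum(phantom: Phantom, axis: str = "y") -> np.ndarray:
    """Orthographic ray-sum preview: glandular weights summed along one axis, uint8."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    sums = phantom.glandular_weights().sum(axis=_AXES[axis], dtype=np.float64)
    lo, hi = float(sums.min()), float(sums.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    return ((sums - lo) * scale).astype(np.uint8)


def save_preview(image: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(image.T[::-1]).save(str(path))


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one simulation run."""

    seed: int = 0
    n_cohort: int = 2000
    n_women: int = 1
    ages: tuple[float, ...] = (40.0, 57.0, 74.0)
    method: str = "A"
    grid_shape: tuple[int, int, int] = (220, 120, 60)
    voxel_mm: float = 1.0
    sf_levels: tuple[float, ...] = (0.93, 0.96, 0.99, 1.02, 1.05)
    n_calibration_phantoms: int = 10
    calibration_path: str | None = None
    volume_cm3: float | None = None  # calibration breast volume; None = population mean, capped to grid
    lesion_d0_mm: float = 0.0  # 0 disables lesion simulation
    lesion_tdt_days: float = 282.0
    lesion_method: int = 3
    rotate_deg: float = 0.0
    out_dir: str = "breastvit_run"

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kw = dict(d)
        for key in ("ages", "grid_shape", "sf_levels"):
            if key in kw:
                kw[key] = tuple(kw[key])
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ages", "grid_shape", "sf_levels"):
            d[key] = list(d[key])
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"config": config.to_dict(), "stages": [], "women": []}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("population")
        spec = cohort_mod.FixtureSpec(n=config.n_cohort, seed=int(rng.integers(2**31 - 1)))
        frame = cohort_mod.generate_cohort_frame(spec)
        cohort_mod.write_cohort_csv(frame, out_dir / "cohort.csv")
        results = fit_copula(frame)
        manifest["copula_nu"] = round(results.nu, 3)

        stage("calibration")
        pspec = PhantomSpec(shape=config.grid_shape, voxel_mm=config.voxel_mm)
        volume = config.volume_cm3
        if volume is None:
            volume = min(848.0, 0.8 * _grid_capacity_cm3(pspec))
        pspec = dataclasses.replace(pspec, volume_cm3=volume)
        if config.calibration_path:
            cal = DensityCalibration.load(config.calibration_path)
        else:
            cal = calibrate_density(
                pspec,
                config.sf_levels,
                n_phantoms=config.n_calibration_phantoms,
                seed=int(rng.integers(2**31 - 1)),
            )
            cal.save(out_dir / "calibration.csv")
        manifest["calibration_vbd_range"] = [round(v, 3) for v in cal.vbd_range]

        stage("timelines")
        women = results.sample(config.n_women, int(rng.integers(2**31 - 1)))
        growth = GrowthModel(config.lesion_d0_mm, config.lesion_tdt_days) if config.lesion_d0_mm else None
        for w in range(config.n_women):
            row = women.iloc[w]
            phantom_seed = int(rng.integers(2**31 - 1))
            tl = build_timeline(
                f"woman{w:03d}",
                config.ages,
                config.method,
                cal,
                growth,
                copula=results,
                start_vbd=float(100.0 * row.dense_volume_cm3 / row.breast_volume_cm3),
                start_volume=float(row.breast_volume_cm3),
                phantom_seed=phantom_seed,
                seed=int(rng.integers(2**31 - 1)),
            )
            entry = {"woman_id": tl.woman_id, "phantom_seed": phantom_seed, "ages": []}
            for k, age in enumerate(tl.ages):
                pspec_k = dataclasses.replace(pspec, volume_cm3=min(tl.volume_series[k], 0.95 * _grid_capacity_cm3(pspec)))
                ph = build_phantom(
                    pspec_k, phantom_seed, pspec.thresholds.with_sf(tl.sf_series[k])
                )
                if growth is not None and tl.tumor_series[k] >= 2 * config.voxel_mm:
                    les = generate_lesion(
                        tl.tumor_series[k], config.lesion_method, seed=phantom_seed,
                        voxel_mm=config.voxel_mm,
                    )
                    nipple = _nipple_voxel(ph)
                    res = ins_mod.auto_insert(
                        ph, les, ins_mod.InsertionPolicy(), nipple,
                        seed=np.random.default_rng([phantom_seed, k]),
                    )
                    ph = res.phantom
                if config.rotate_deg and k > 0:
                    from .phantom import rotate_phantom

                    ph = rotate_phantom(
                        ph, seed=phantom_seed + k, angle_range_deg=config.rotate_deg
                    )
                base = out_dir / f"{tl.woman_id}_age{age:g}"
                save_phantom(ph, base)
                save_preview(project_raysum(ph, "y"), base.with_suffix(".png"))
                entry["ages"].append(
                    {
                        "age": age,
                        "target_vbd": round(tl.vbd_series[k], 3),
                        "achieved_vbd": round(compute_vbd(ph), 3),
                        "volume_cm3": round(tl.volume_series[k], 1),
                        "sf": round(tl.sf_series[k], 4),
                        "tumor_mm": round(tl.tumor_series[k], 2) if tl.tumor_series else None,
                    }
                )
            manifest["women"].append(entry)
    except Exception as err:
        failed_stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["error"] = {"stage": failed_stage, "message": str(err)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {failed_stage!r}: {err}") from err

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = [
        {"woman_id": w["woman_id"], **a} for w in manifest["women"] for a in w["ages"]
    ]
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _grid_capacity_cm3(spec: PhantomSpec) -> float:
    nx, ny, nz = spec.shape
    import math

    ts = np.linspace(0.0, 1.0, 513)
    integral = float(np.trapezoid((1.0 - ts**spec.taper_exponent) ** (2.0 / spec.taper_exponent), ts))
    vmax = math.pi * ((nx - 1) / 2) * ((nz - 1) / 2) * (ny - 1) * integral
    return vmax * (spec.voxel_mm / 10.0) ** 3


def _nipple_voxel(ph: Phantom) -> tuple[int, int, int]:
    """Anterior-most breast voxel on the mid axis: the outline's nipple."""
    ys = np.nonzero(ph.breast_mask.any(axis=(0, 2)))[0]
    y = int(ys.max())
    sl = ph.breast_mask[:, y, :]
    xs, zs = np.nonzero(sl)
    return (int(np.median(xs)), y, int(np.median(zs)))
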