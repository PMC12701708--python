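"""Procedural 3D tissue texture: fractal Perlin gradient noise and density thresholding.

Breast parenchyma is emulated as a layered random texture: classic lattice
gradient noise ("Perlin noise") is evaluated in 3D, several octaves of
increasing spatial frequency are superimposed, and a tunable threshold turns
the continuous field into binary glandular structures.  The threshold (scaled
by a global scaling factor, SF) controls how much of the volume becomes dense
tissue, which is what the density calibration in :func:`calibrate_density`
exploits: raising SF only removes structure voxels, never adds them, so the
same noise realization can be re-thresholded to emulate tissue involution.

All fields are pure functions of ``(seed, params, shape)``: gradients are
drawn once per (seed, octave) on a lattice sized to the full volume, so the
same field can be evaluated slab-by-slab for large grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PerlinParams",
    "ThresholdSpec",
    "DensityCalibration",
    "perlin_field",
    "fractal_field",
    "perlin_at_points",
    "fractal_at_points",
    "threshold_structures",
    "calibrate_density",
    "sf_for_density",
]

#: Theoretical half-range of 3D unit-gradient lattice noise with quintic fade.
_AMPLITUDE = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class PerlinParams:
    """Parameters of one fractal-noise block.

    ``base_frequency`` counts lattice cells along the longest edge of the
    evaluated volume, so a frequency of 12 on a 220 mm grid gives coarsest
    structures of roughly 18 mm — the scale of real glandular texture.
    ``lacunarity`` multiplies the frequency per octave and ``persistence``
    multiplies the amplitude, as is conventional for fractal noise.
    """

    seed: int
    octaves: int = 4
    lacunarity: float = 2.0
    persistence: float = 0.5
    base_frequency: float = 12.0
    voxel_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.lacunarity <= 1.0:
            raise ValueError("lacunarity must be > 1")
        if not 0.0 < self.persistence <= 1.0:
            raise ValueError("persistence must be in (0, 1]")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-block base thresholds plus the global scaling factor SF.

    The effective threshold of block *i* is ``clip(scaling_factor *
    base_thresholds[i], 0, 1)``.  A threshold of 1 produces no structures,
    a threshold of 0 fills the whole volume.
    """

    base_thresholds: tuple[float, ...]
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        for t in self.base_thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"base threshold {t} outside [0, 1]")
        if self.scaling_factor < 0:
            raise ValueError("scaling_factor must be non-negative")

    def effective(self, block: int = 0) -> float:
        return float(np.clip(self.scaling_factor * self.base_thresholds[block], 0.0, 1.0))

    def with_sf(self, sf: float) -> "ThresholdSpec":
        return replace(self, scaling_factor=sf)


def _gradients(seed: int, octave: int, n_nodes: tuple[int, int, int]) -> np.ndarray:
    """Seeded random unit gradient vectors on the lattice nodes of one octave."""
    rng = np.random.default_rng([abs(int(seed)), int(octave), 0x9E3779B9])
    g = rng.standard_normal(size=(*n_nodes, 3))
    norm = np.linalg.norm(g, axis=-1, keepdims=True)
    # degenerate zero vectors are measure-zero; guard anyway
    norm[norm == 0] = 1.0
    return g / norm


def _fade(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep 6t^5 - 15t^4 + 10t^3 (zero first and second derivative at nodes)."""
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _perlin_raw(pts: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Raw gradient noise at lattice-space points ``pts`` (..., 3), range ±sqrt(3)/2."""
    n_nodes = grads.shape[:3]
    i0 = np.floor(pts).astype(np.intp)
    for ax in range(3):
        np.clip(i0[..., ax], 0, n_nodes[ax] - 2, out=i0[..., ax])
    f = pts - i0
    u = _fade(f)
    out = np.zeros(pts.shape[:-1])
    for cx in (0, 1):
        wx = u[..., 0] if cx else 1.0 - u[..., 0]
        for cy in (0, 1):
            wy = u[..., 1] if cy else 1.0 - u[..., 1]
            for cz in (0, 1):
                wz = u[..., 2] if cz else 1.0 - u[..., 2]
                g = grads[i0[..., 0] + cx, i0[..., 1] + cy, i0[..., 2] + cz]
                dot = (
                    g[..., 0] * (f[..., 0] - cx)
                    + g[..., 1] * (f[..., 1] - cy)
                    + g[..., 2] * (f[..., 2] - cz)
                )
                out += wx * wy * wz * dot
    return out


def _octave_freq(params: PerlinParams, octave: int) -> float:
    return params.base_frequency * params.lacunarity**octave


def _grid_lattice_points(
    shape: Sequence[int], freq: float, zrange: tuple[int, int] | None
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Voxel-index coordinates mapped to lattice space, plus node counts sized to the full grid."""
    nx, ny, nz = (int(s) for s in shape)
    if min(nx, ny, nz) < 1:
        raise ValueError(f"shape must be positive in all dimensions, got {shape!r}")
    scale = freq / max(nx, ny, nz)
    n_nodes = tuple(int(math.floor((s - 1) * scale)) + 2 for s in (nx, ny, nz))
    z0, z1 = (0, nz) if zrange is None else zrange
    xs = np.arange(nx) * scale
    ys = np.arange(ny) * scale
    zs = np.arange(z0, z1) * scale
    pts = np.empty((nx, ny, z1 - z0, 3))
    pts[..., 0] = xs[:, None, None]
    pts[..., 1] = ys[None, :, None]
    pts[..., 2] = zs[None, None, :]
    return pts, n_nodes  # type: ignore[return-value]


def perlin_field(
    params: PerlinParams,
    shape: Sequence[int],
    *,
    octave: int = 0,
    zrange: tuple[int, int] | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Single-octave gradient noise on a voxel grid.

    With ``rescale=True`` (default) the raw values, theoretically bounded by
    ±sqrt(3)/2, are mapped affinely onto [0, 1] so that thresholds are
    comparable across blocks and phantoms.  ``zrange=(z0, z1)`` evaluates only
    a slab of the full grid with identical values, enabling tiled processing.
    """
    pts, n_nodes = _grid_lattice_points(shape, _octave_freq(params, octave), zrange)
    raw = _perlin_raw(pts, _gradients(params.seed, octave, n_nodes))
    if not rescale:
        return raw
    return 0.5 + raw / (2.0 * _AMPLITUDE)


def fractal_field(
    params: PerlinParams,
    shape: Sequence[int],
    *,
    zrange: tuple[int, int] | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Sum of ``octaves`` noise layers, amplitude-normalized by the geometric sum.

    The normalizer is the theoretical amplitude sum ``Σ persistence**o`` (not a
    per-volume min/max), so the [0, 1] mapping — and hence any threshold — is
    transferable between phantoms and seeds.
    """
    total = None
    amp_sum = 0.0
    for o in range(params.octaves):
        amp = params.persistence**o
        layer = amp * perlin_field(params, shape, octave=o, zrange=zrange, rescale=False)
        total = layer if total is None else total + layer
        amp_sum += amp
    raw = total / amp_sum
    if not rescale:
        return raw
    return 0.5 + raw / (2.0 * _AMPLITUDE)


def perlin_at_points(
    params: PerlinParams, points: np.ndarray, *, octave: int = 0, rescale: bool = True
) -> np.ndarray:
    """Gradient noise at arbitrary points in the unit cube [0, 1]^3.

    Used for size-normalized evaluation (lesion margins, interior texture):
    the point coordinates, not a voxel grid, define the frame, so the same
    seed yields the same values at the same relative positions regardless of
    the physical size of the object being textured.
    """
    points = np.asarray(points, dtype=float)
    freq = _octave_freq(params, octave)
    n = int(math.floor(freq)) + 2
    pts = np.clip(points, 0.0, 1.0) * freq
    raw = _perlin_raw(pts, _gradients(params.seed, octave, (n, n, n)))
    if not rescale:
        return raw
    return 0.5 + raw / (2.0 * _AMPLITUDE)


def fractal_at_points(params: PerlinParams, points: np.ndarray, *, rescale: bool = True) -> np.ndarray:
    total = None
    amp_sum = 0.0
    for o in range(params.octaves):
        amp = params.persistence**o
        layer = amp * perlin_at_points(params, points, octave=o, rescale=False)
        total = layer if total is None else total + layer
        amp_sum += amp
    raw = total / amp_sum
    if not rescale:
        return raw
    return 0.5 + raw / (2.0 * _AMPLITUDE)


def threshold_structures(field_01: np.ndarray, spec: ThresholdSpec, *, block: int = 0) -> np.ndarray:
    """Binary structure mask: voxel is structure iff field value >= effective threshold.

    An effective threshold of 1 yields an empty mask (no structures); 0 fills
    the volume.  For a fixed field the structure set shrinks monotonically as
    the threshold rises — raising SF removes structures without adding any,
    which is the mechanism used to emulate glandular involution.
    """
    fmin, fmax = float(np.min(field_01)), float(np.max(field_01))
    if fmin < 0.0 or fmax > 1.0:
        raise ValueError("field values must lie in [0, 1]; pass a rescaled field")
    return field_01 >= spec.effective(block)


# ---------------------------------------------------------------------------
# Density calibration: SF -> achieved volumetric breast density
# ---------------------------------------------------------------------------


@dataclass
class DensityCalibration:
    """Mapping between threshold scaling factor and achieved density.

    ``levels`` holds one ``(sf, mean_vbd, sd_vbd)`` row per calibrated SF
    level (mean/sd over independently seeded phantoms).  ``curve_params``
    are the coefficients of the fitted monotone curve
    ``vbd(SF) = exp(q0 + q1 SF + q2 SF^2)`` (a quadratic in log density,
    strictly decreasing over the calibrated range), used for interpolation in
    both directions.  No extrapolation outside the calibrated range is
    allowed.
    """

    levels: list[tuple[float, float, float]]
    curve_params: tuple[float, float, float]
    sf_range: tuple[float, float] = field(init=False)
    vbd_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        sfs = [lv[0] for lv in self.levels]
        self.sf_range = (min(sfs), max(sfs))
        q0, q1, q2 = self.curve_params
        for sf in self.sf_range:
            if q1 + 2.0 * q2 * sf >= 0:
                raise ValueError("fitted calibration curve is not decreasing over the SF range")
        means = [lv[1] for lv in self.levels]
        # densities reachable by interpolation: union of the curve endpoints and
        # the level means (fit residuals can leave a mean marginally outside
        # the curve's span)
        self.vbd_range = (
            min(self.predict(self.sf_range[1]), min(means)),
            max(self.predict(self.sf_range[0]), max(means)),
        )

    def predict(self, sf: float) -> float:
        q0, q1, q2 = self.curve_params
        return float(math.exp(q0 + q1 * sf + q2 * sf * sf))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.levels, columns=["sf", "mean_vbd_pct", "sd_vbd_pct"])

    def save(self, path) -> None:
        import json

        frame = self.to_frame()
        frame.to_csv(str(path), index=False)
        with open(str(path) + ".curve.json", "w") as fh:
            json.dump({"log_quadratic": list(self.curve_params)}, fh)

    @classmethod
    def load(cls, path) -> "DensityCalibration":
        import json

        import pandas as pd

        frame = pd.read_csv(str(path))
        with open(str(path) + ".curve.json") as fh:
            p = json.load(fh)
        levels = [tuple(r) for r in frame[["sf", "mean_vbd_pct", "sd_vbd_pct"]].itertuples(index=False)]
        return cls(levels=levels, curve_params=tuple(p["log_quadratic"]))


def calibrate_density(
    phantom_spec,
    sf_levels: Sequence[float],
    n_phantoms: int = 10,
    *,
    seed: int = 0,
) -> DensityCalibration:
    """Calibrate the SF → VBD% relation on replicate phantoms.

    For each SF level, ``n_phantoms`` phantoms with independent seeds are
    built and their volumetric breast density computed; a monotone
    exponential-decay curve is then fitted to the per-level means.  Because
    thresholding the *same* noise field at every SF level is exact, the noise
    fields are generated once per seed and re-thresholded, which is both
    faster and variance-free across levels.
    """
    from .phantom import build_phantom_fields, compute_vbd, phantom_noise_fields

    sf_levels = sorted(float(s) for s in sf_levels)
    if len(sf_levels) < 2:
        raise ValueError("need at least 2 SF levels to calibrate")
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")

    vbd = np.empty((len(sf_levels), n_phantoms))
    root = np.random.default_rng(seed)
    phantom_seeds = root.integers(0, 2**31 - 1, size=n_phantoms)
    for j, ps in enumerate(phantom_seeds):
        fields, outline = phantom_noise_fields(phantom_spec, int(ps))
        for i, sf in enumerate(sf_levels):
            ph = build_phantom_fields(
                phantom_spec, fields, outline, phantom_spec.thresholds.with_sf(sf), seed=int(ps)
            )
            vbd[i, j] = compute_vbd(ph)

    means = vbd.mean(axis=1)
    sds = vbd.std(axis=1, ddof=1) if n_phantoms > 1 else np.zeros(len(sf_levels))
    if np.any(np.diff(means) > 0) or np.any(means <= 0):
        raise ValueError(
            "per-level mean VBD is not positive and monotone decreasing in SF; "
            f"levels={sf_levels}, means={means.round(3).tolist()} — "
            "increase n_phantoms or widen the SF spacing"
        )

    # quadratic in log density: near-linear for threshold-on-noise, strictly monotone
    if len(sf_levels) == 2:
        q1 = (math.log(means[1]) - math.log(means[0])) / (sf_levels[1] - sf_levels[0])
        coeffs = (math.log(means[0]) - q1 * sf_levels[0], q1, 0.0)
    else:
        q2, q1, q0 = np.polyfit(sf_levels, np.log(means), 2)
        coeffs = (float(q0), float(q1), float(q2))
    levels = [(sf_levels[i], float(means[i]), float(sds[i])) for i in range(len(sf_levels))]
    return DensityCalibration(levels=levels, curve_params=coeffs)


def sf_for_density(cal: DensityCalibration, target_vbd: float) -> float:
    """Invert the fitted calibration curve: SF that yields the target VBD%.

    The target must lie inside the calibrated density range; the curve is
    strictly monotone so bisection converges to machine-level tolerance.
    """
    from scipy.optimize import brentq

    lo, hi = cal.vbd_range
    if not lo <= target_vbd <= hi:
        raise ValueError(
            f"target VBD {target_vbd:.2f}% outside calibrated range [{lo:.2f}, {hi:.2f}]%; "
            "no extrapolation"
        )
    sf_lo, sf_hi = cal.sf_range
    # targets inside the level-mean range but marginally past a curve endpoint
    # (fit residual) clamp to that endpoint's SF
    if target_vbd >= cal.predict(sf_lo):
        return sf_lo
    if target_vbd <= cal.predict(sf_hi):
        return sf_hi
    return float(brentq(lambda sf: cal.predict(sf) - target_vbd, sf_lo, sf_hi, xtol=1e-6))
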