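"""Procedural soft-tissue lesions and their growth over time.

A lesion is a sphere whose surface radius is perturbed by low-frequency
gradient noise evaluated on the *unit direction* of each voxel, so the margin
pattern is a pure function of the seed and is preserved when the lesion is
regrown at a larger diameter — regrowing reuses the same noise on the scaled
surface, which is how lesion progression over screening rounds is simulated.

Three composition methods are supported:

1. homogeneous — uniform dense-tissue material inside the margin;
2. background-enhancing — host-tissue glandular weights inside the lesion are
   multiplied by a contrast factor (heterogeneity inherited from the phantom);
3. background-enhancing plus an interior fractal-noise texture evaluated in a
   size-normalized frame, adding lesion-intrinsic heterogeneity.

Growth follows the linear-diameter convention: the diameter doubles after one
"tumor volume doubling time" period (the worked clinical example: 5 mm grows
to 10 mm after one 282-day period and to ~18 mm after two years).  A strict
volume-doubling mode (``d * 2**(t / (3*tdt))``) is available behind a flag
for users who prefer the literal reading of the doubling time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .texture import PerlinParams, fractal_at_points, perlin_at_points

__all__ = [
    "Lesion",
    "GrowthModel",
    "DEFAULT_TDT_DAYS",
    "TDT_RANGE_DAYS",
    "generate_lesion",
    "regrow_lesion",
    "grown_diameter",
    "sample_tdt",
]

#: mean clinical tumor volume doubling time (days) and its observed range
DEFAULT_TDT_DAYS = 282.0
TDT_RANGE_DAYS = (46.0, 749.0)


@dataclass(frozen=True)
class GrowthModel:
    """Linear-diameter tumor growth: d(t) = d0 * (1 + t / tdt)."""

    d0: float  # initial diameter, mm
    tdt: float = DEFAULT_TDT_DAYS  # doubling period, days

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("initial diameter must be positive")
        if self.tdt <= 0:
            raise ValueError("doubling time must be positive")


def grown_diameter(g: GrowthModel, t_days: float, *, volume_doubling: bool = False) -> float:
    """Diameter in mm after ``t_days`` of growth.

    Default: linear diameter, doubling the diameter per ``tdt``.  With
    ``volume_doubling=True`` the *volume* doubles per ``tdt`` instead
    (diameter factor 2**(t/(3*tdt))).
    """
    if t_days < 0:
        raise ValueError("time must be non-negative")
    if volume_doubling:
        return g.d0 * 2.0 ** (t_days / (3.0 * g.tdt))
    return g.d0 * (1.0 + t_days / g.tdt)


def sample_tdt(rng: np.random.Generator, mean: float = DEFAULT_TDT_DAYS,
               sd: float = 150.0, bounds: tuple[float, float] = TDT_RANGE_DAYS) -> float:
    """Draw one doubling time from a normal truncated to the observed clinical range."""
    from scipy import stats

    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass
class Lesion:
    """Voxelized lesion within its bounding box.

    ``occupancy`` is the boolean mass mask; ``interior`` (method 3 only) is a
    [0, 1] texture field over the bounding box used for heterogeneous
    composition at insertion time.
    """

    occupancy: np.ndarray
    diameter: float  # mm, declared largest-axis size
    method: int  # 1 homogeneous | 2 background-enhancing | 3 enhancing + interior noise
    seed: int
    voxel_mm: float
    enhancement: float = 1.5
    margin_amplitude: float = 0.1
    margin_frequency: float = 3.0
    interior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ValueError("method must be 1, 2 or 3")
        if self.method == 3 and self.interior is None:
            raise ValueError("method 3 requires an interior texture field")

    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * self.voxel_mm**3

    def extent_mm(self) -> tuple[float, float, float]:
        """Occupied extent along each axis (largest-axis extent ~ diameter)."""
        idx = np.nonzero(self.occupancy)
        return tuple((idx[k].max() - idx[k].min() + 1) * self.voxel_mm for k in range(3))


def _margin_noise(directions: np.ndarray, seed: int, frequency: float) -> np.ndarray:
    """Signed margin perturbation in [-1, 1] for unit direction vectors."""
    params = PerlinParams(seed=seed, octaves=1, base_frequency=frequency, voxel_mm=1.0)
    pts = (directions + 1.0) / 2.0  # unit ball -> unit cube
    raw = perlin_at_points(params, pts, rescale=False)
    return np.clip(raw / (np.sqrt(3.0) / 2.0), -1.0, 1.0)


def generate_lesion(
    diameter_mm: float,
    method: int = 1,
    seed: int = 0,
    *,
    voxel_mm: float = 1.0,
    margin_amplitude: float = 0.1,
    margin_frequency: float = 3.0,
    enhancement: float = 1.5,
    interior_params: PerlinParams | None = None,
) -> Lesion:
    """Voxelize an irregular lesion of the given diameter.

    The surface radius is ``(d/2) * (1 + a * n(direction))`` with ``n`` a
    low-frequency noise field on the unit sphere and ``a`` the margin
    amplitude; with ``a = 0`` the lesion is an exact voxelized sphere.  The
    noise frame is size-normalized, so the same seed at a different diameter
    yields the same relative margin profile.
    """
    if diameter_mm < 2.0 * voxel_mm:
        raise ValueError(
            f"diameter {diameter_mm} mm below the resolvable minimum of {2 * voxel_mm} mm"
        )
    if not 0.0 <= margin_amplitude < 1.0:
        raise ValueError("margin_amplitude must be in [0, 1)")
    r_vox = diameter_mm / 2.0 / voxel_mm
    half = int(np.ceil(r_vox * (1.0 + margin_amplitude))) + 1
    n = 2 * half + 1
    ax = np.arange(n) - half
    px, py, pz = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = np.sqrt(px**2 + py**2 + pz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack([px, py, pz], axis=-1) / np.where(dist == 0, 1.0, dist)[..., None]
    if margin_amplitude > 0:
        noise = _margin_noise(dirs, seed, margin_frequency)
    else:
        noise = np.zeros_like(dist)
    radius = r_vox * (1.0 + margin_amplitude * noise)
    occupancy = dist <= radius
    interior = None
    if method == 3:
        if interior_params is None:
            interior_params = PerlinParams(
                seed=seed + 1, octaves=3, base_frequency=4.0, voxel_mm=voxel_mm
            )
        # size-normalized frame: interior texture scales with the lesion
        pts = np.stack([px, py, pz], axis=-1) / (2.0 * r_vox * (1.0 + margin_amplitude)) + 0.5
        interior = fractal_at_points(interior_params, pts.reshape(-1, 3)).reshape(dist.shape)
    return Lesion(
        occupancy=occupancy,
        diameter=diameter_mm,
        method=method,
        seed=seed,
        voxel_mm=voxel_mm,
        enhancement=enhancement,
        margin_amplitude=margin_amplitude,
        margin_frequency=margin_frequency,
        interior=interior,
    )


def regrow_lesion(lesion: Lesion, new_diameter_mm: float) -> Lesion:
    """Regenerate the lesion at a new diameter with identical seed and margin pattern."""
    return generate_lesion(
        new_diameter_mm,
        lesion.method,
        lesion.seed,
        voxel_mm=lesion.voxel_mm,
        margin_amplitude=lesion.margin_amplitude,
        margin_frequency=lesion.margin_frequency,
        enhancement=lesion.enhancement,
    )
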