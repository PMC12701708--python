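"""Voxel breast phantoms: outline, assembly from texture blocks, density, rotation, I/O.

A phantom is a 3D grid of small integer tissue indices plus a material table
mapping each index to a glandular weight ``w_g`` in [0, 1] (0 = pure adipose,
1 = pure glandular; index 0 is reserved for outside-breast air).  Volumetric
breast density (VBD%) is the glandular-weighted voxel sum divided by the
number of breast voxels.

Coordinate convention: ``x`` = medial–lateral, ``y`` = posterior→anterior
(chest wall at y = 0, nipple toward y = ny), ``z`` = inferior–superior.
Assembly is slab-wise along ``z`` so full-scale grids (2200×1200×600 voxels
at 0.1 mm) never need more than one texture slab resident at a time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .texture import PerlinParams, ThresholdSpec, fractal_field

__all__ = [
    "AIR_INDEX",
    "ADIPOSE_INDEX",
    "GLANDULAR_INDEX",
    "LESION_INDEX",
    "DEFAULT_MATERIALS",
    "OutlineGeometry",
    "PhantomSpec",
    "Phantom",
    "solve_outline",
    "make_outline",
    "build_phantom",
    "assemble_phantom",
    "phantom_noise_fields",
    "build_phantom_fields",
    "compute_vbd",
    "rotate_phantom",
    "save_phantom",
    "load_phantom",
]

AIR_INDEX = 0
ADIPOSE_INDEX = 1
#: indices 2..11 form a glandular-weight ramp w_g = (i-1)/10; 11 is pure glandular
GLANDULAR_INDEX = 11
LESION_INDEX = 12

#: Default material table.  Weights are configuration, not physics constants:
#: the glandular/adipose mix per index is expected to be tuned against the
#: attenuation tables of whatever projection tool consumes the phantom.
DEFAULT_MATERIALS: dict[int, float] = {ADIPOSE_INDEX: 0.0}
DEFAULT_MATERIALS.update({i: (i - 1) / 10.0 for i in range(2, 12)})
DEFAULT_MATERIALS[LESION_INDEX] = 1.0


def weight_to_index(w: float) -> int:
    """Nearest tissue index on the adipose→glandular ramp for weight ``w``."""
    q = int(round(float(np.clip(w, 0.0, 1.0)) * 10.0))
    return ADIPOSE_INDEX if q == 0 else q + 1


# ---------------------------------------------------------------------------
# Breast outline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlineGeometry:
    """Breast outline: superelliptic-tapered half-ellipsoid with flat chest wall.

    The chest-wall face is the y = 0 plane.  At height ``y`` the cross
    section is an ellipse with semi-axes ``(a*g, c*g)`` where
    ``g = (1 - (y/b)**p)**(1/p)``; ``p = 2`` is the exact half-ellipsoid and
    larger ``p`` gives a blunter outline that fills more of the grid.
    """

    shape: tuple[int, int, int]
    voxel_mm: float
    a: float  # semi-axis along x, voxels
    b: float  # extent along y from the chest wall, voxels
    c: float  # semi-axis along z, voxels
    p: float = 3.0

    @property
    def center_x(self) -> float:
        return (self.shape[0] - 1) / 2.0

    @property
    def center_z(self) -> float:
        return (self.shape[2] - 1) / 2.0

    def _cross_section(self, y: float) -> float:
        """Taper factor g(y) in [0, 1]; 0 outside the breast."""
        t = y / self.b
        if t < 0 or t >= 1.0:
            return 0.0
        return (1.0 - t**self.p) ** (1.0 / self.p)

    def voxel_count(self) -> int:
        """Exact voxel count by column arithmetic — O(nx) per slice, any grid scale."""
        nx, ny, nz = self.shape
        total = 0
        xs = np.arange(nx) - self.center_x
        for iy in range(ny):
            g = self._cross_section(float(iy))
            if g <= 0.0:
                continue
            ay, cy = self.a * g, self.c * g
            inside = np.abs(xs) <= ay
            if not inside.any():
                continue
            half = cy * np.sqrt(np.maximum(0.0, 1.0 - (xs[inside] / ay) ** 2))
            zhi = np.floor(self.center_z + half)
            zlo = np.ceil(self.center_z - half)
            np.clip(zhi, -1, nz - 1, out=zhi)
            np.clip(zlo, 0, nz, out=zlo)
            total += int(np.maximum(0, zhi - zlo + 1).sum())
        return total

    def mask(self, zrange: tuple[int, int] | None = None) -> np.ndarray:
        nx, ny, nz = self.shape
        z0, z1 = (0, nz) if zrange is None else zrange
        xs = (np.arange(nx) - self.center_x)[:, None, None]
        ys = np.arange(ny)[None, :, None].astype(float)
        zs = (np.arange(z0, z1) - self.center_z)[None, None, :]
        t = np.clip(ys / self.b, 0.0, None)
        g = np.where(t < 1.0, (1.0 - np.minimum(t, 1.0) ** self.p) ** (1.0 / self.p), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (xs / (self.a * g)) ** 2 + (zs / (self.c * g)) ** 2
        out = np.where(g > 0.0, r2, np.inf) <= 1.0
        return out

    def volume_cm3(self) -> float:
        return self.voxel_count() * (self.voxel_mm / 10.0) ** 3


def solve_outline(
    target_volume_cm3: float,
    shape: Sequence[int],
    voxel_mm: float,
    *,
    taper_exponent: float = 3.0,
    margin: float = 0.995,
) -> OutlineGeometry:
    """Size a breast outline so its voxel volume matches the target within 1%."""
    nx, ny, nz = (int(s) for s in shape)
    if target_volume_cm3 <= 0:
        raise ValueError("target volume must be positive")
    target_voxels = target_volume_cm3 * 1000.0 / voxel_mm**3
    a_max = margin * (nx - 1) / 2.0
    b_max = margin * (ny - 1)
    c_max = margin * (nz - 1) / 2.0
    p = taper_exponent
    # continuous volume: pi * a * c * b * I(p), I(p) = ∫0..1 (1-t^p)^(2/p) dt
    ts = np.linspace(0.0, 1.0, 2049)
    integral = float(np.trapezoid((1.0 - ts**p) ** (2.0 / p), ts))
    v_max = math.pi * a_max * c_max * b_max * integral
    s = (target_voxels / v_max) ** (1.0 / 3.0)
    if s > 1.0:
        raise ValueError(
            f"target volume {target_volume_cm3:.0f} cm^3 does not fit the "
            f"{nx}x{ny}x{nz} grid at {voxel_mm} mm (max ~{v_max * (voxel_mm / 10.0) ** 3:.0f} cm^3)"
        )
    geom = OutlineGeometry(
        shape=(nx, ny, nz), voxel_mm=voxel_mm, a=s * a_max, b=s * b_max, c=s * c_max, p=p
    )
    # a couple of Newton-style corrections on the discrete count
    for _ in range(3):
        count = geom.voxel_count()
        if count == 0:
            raise ValueError("target volume too small to resolve on this grid")
        ratio = (target_voxels / count) ** (1.0 / 3.0)
        if abs(ratio - 1.0) < 2.5e-3:
            break
        s = min(s * ratio, 1.0)
        geom = OutlineGeometry(
            shape=(nx, ny, nz), voxel_mm=voxel_mm, a=s * a_max, b=s * b_max, c=s * c_max, p=p
        )
    achieved = geom.volume_cm3()
    if abs(achieved - target_volume_cm3) > 0.01 * target_volume_cm3:
        raise ValueError(
            f"outline solver achieved {achieved:.1f} cm^3 for target {target_volume_cm3:.1f} cm^3"
        )
    return geom


def make_outline(
    target_volume_cm3: float, shape: Sequence[int], voxel_mm: float, *, taper_exponent: float = 3.0
) -> np.ndarray:
    """Boolean breast mask whose volume matches the target within 1%."""
    return solve_outline(target_volume_cm3, shape, voxel_mm, taper_exponent=taper_exponent).mask()


# ---------------------------------------------------------------------------
# Phantom assembly
# ---------------------------------------------------------------------------


def default_blocks(voxel_mm: float = 1.0) -> tuple[PerlinParams, PerlinParams]:
    """Two texture blocks: coarse glandular lobes plus fine connective strands."""
    return (
        PerlinParams(seed=0, octaves=4, lacunarity=2.0, persistence=0.5, base_frequency=12.0, voxel_mm=voxel_mm),
        PerlinParams(seed=0, octaves=3, lacunarity=2.0, persistence=0.5, base_frequency=32.0, voxel_mm=voxel_mm),
    )


DEFAULT_THRESHOLDS = ThresholdSpec(base_thresholds=(0.60, 0.66), scaling_factor=1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build one phantom except the seed and the SF."""

    shape: tuple[int, int, int] = (220, 120, 60)
    voxel_mm: float = 1.0
    volume_cm3: float = 848.0
    blocks: tuple[PerlinParams, ...] = field(default_factory=default_blocks)
    thresholds: ThresholdSpec = DEFAULT_THRESHOLDS
    taper_exponent: float = 3.0
    material_table: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_MATERIALS))
    block_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.thresholds.base_thresholds) != len(self.blocks):
            raise ValueError("one base threshold per texture block is required")

    def indices(self) -> tuple[int, ...]:
        if self.block_indices is not None:
            return self.block_indices
        return tuple(GLANDULAR_INDEX for _ in self.blocks)


@dataclass
class Phantom:
    """Voxel phantom: tissue-index grid + material table + breast mask."""

    voxels: np.ndarray  # uint8, shape (nx, ny, nz)
    material_table: dict[int, float]
    breast_mask: np.ndarray  # bool, same shape
    voxel_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxels.shape != self.breast_mask.shape:
            raise ValueError("voxels and breast_mask must share dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def glandular_weights(self) -> np.ndarray:
        """Per-voxel w_g as float32 (air = 0)."""
        lut = np.zeros(max(self.material_table) + 1, dtype=np.float32)
        for idx, w in self.material_table.items():
            lut[idx] = w
        present = np.unique(self.voxels)
        missing = [int(i) for i in present if i != AIR_INDEX and int(i) not in self.material_table]
        if missing:
            raise ValueError(f"material table missing indices {missing}")
        return lut[self.voxels]


def _block_seed(phantom_seed: int, block: int) -> int:
    return int((phantom_seed * 1000003 + 7919 * (block + 1)) % (2**31 - 1))


def phantom_noise_fields(spec: PhantomSpec, seed: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Materialize the per-block fractal fields and the outline mask for one seed.

    Exposed separately so density calibration can re-threshold the *same*
    fields at many SF values without regenerating the noise.
    """
    geom = solve_outline(spec.volume_cm3, spec.shape, spec.voxel_mm, taper_exponent=spec.taper_exponent)
    outline = geom.mask()
    fields = []
    for b, params in enumerate(spec.blocks):
        fields.append(fractal_field(replace(params, seed=_block_seed(seed, b)), spec.shape))
    return fields, outline


def assemble_phantom(
    outline: np.ndarray,
    block_fields: Sequence[np.ndarray],
    thresholds: ThresholdSpec,
    material_table: Mapping[int, float],
    *,
    block_indices: Sequence[int] | None = None,
    voxel_mm: float = 1.0,
    provenance: dict | None = None,
) -> Phantom:
    """Label inside-breast voxels from thresholded texture blocks.

    A voxel becomes a structure voxel of block *i* when block *i*'s field
    exceeds its effective threshold; later blocks override earlier ones.
    Remaining breast voxels are adipose; outside voxels carry the air index.
    """
    if block_indices is None:
        block_indices = [GLANDULAR_INDEX] * len(block_fields)
    required = set(block_indices) | {ADIPOSE_INDEX}
    missing = sorted(i for i in required if i not in material_table)
    if missing:
        raise ValueError(f"material table missing required indices {missing}")
    vox = np.full(outline.shape, AIR_INDEX, dtype=np.uint8)
    vox[outline] = ADIPOSE_INDEX
    for b, fld in enumerate(block_fields):
        mask = (fld >= thresholds.effective(b)) & outline
        vox[mask] = block_indices[b]
    return Phantom(
        voxels=vox,
        material_table=dict(material_table),
        breast_mask=outline.copy(),
        voxel_mm=voxel_mm,
        provenance=dict(provenance or {}),
    )


def build_phantom_fields(
    spec: PhantomSpec,
    fields: Sequence[np.ndarray],
    outline: np.ndarray,
    thresholds: ThresholdSpec,
    *,
    seed: int,
) -> Phantom:
    return assemble_phantom(
        outline,
        fields,
        thresholds,
        spec.material_table,
        block_indices=spec.indices(),
        voxel_mm=spec.voxel_mm,
        provenance={"seed": int(seed), "sf": thresholds.scaling_factor, "volume_cm3": spec.volume_cm3},
    )


def build_phantom(spec: PhantomSpec, seed: int, thresholds: ThresholdSpec | None = None) -> Phantom:
    """Build one phantom: outline + thresholded fractal texture blocks."""
    thresholds = thresholds if thresholds is not None else spec.thresholds
    fields, outline = phantom_noise_fields(spec, seed)
    return build_phantom_fields(spec, fields, outline, thresholds, seed=seed)


def compute_vbd(phantom: Phantom) -> float:
    """Volumetric breast density in percent.

    ``100 * Σ_breast w_g(voxel) / N_breast``; air voxels are excluded from
    numerator and denominator.
    """
    n = int(phantom.breast_mask.sum())
    if n == 0:
        raise ValueError("empty breast mask")
    w = phantom.glandular_weights()
    return float(100.0 * w[phantom.breast_mask].sum(dtype=np.float64) / n)


# ---------------------------------------------------------------------------
# Repositioning
# ---------------------------------------------------------------------------


def _rotation_matrix(angles_deg: Sequence[float]) -> np.ndarray:
    ax, ay, az = (math.radians(a) for a in angles_deg)
    def rot(c, s, axis):
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s if axis != 1 else s
        m[j, i] = s if axis != 1 else -s
        return m
    mats = [rot(math.cos(t), math.sin(t), k) for k, t in enumerate((ax, ay, az))]
    r = mats[2] @ mats[1] @ mats[0]
    # snap values that are numerically 0/±1 so lattice-exact angles stay exact
    r[np.abs(r) < 1e-12] = 0.0
    r[np.abs(r - 1.0) < 1e-12] = 1.0
    r[np.abs(r + 1.0) < 1e-12] = -1.0
    return r


def rotate_phantom(
    phantom: Phantom,
    angles_deg: Sequence[float] | None = None,
    *,
    seed: int | None = None,
    angle_range_deg: float = 5.0,
    center: str = "centroid",
) -> Phantom:
    """Rigid rotation about x, y, z with nearest-neighbor resampling.

    Emulates repositioning between screening visits.  With ``seed`` given and
    no explicit angles, small angles are drawn uniformly from
    ``±angle_range_deg``.  Nearest-neighbor interpolation preserves the
    original tissue indices: the output contains only values present in the
    input plus air fill.
    """
    from scipy import ndimage

    if angles_deg is None:
        if seed is None:
            raise ValueError("give explicit angles or a seed to draw them")
        rng = np.random.default_rng(seed)
        angles_deg = rng.uniform(-angle_range_deg, angle_range_deg, size=3)
    angles_deg = [float(a) for a in angles_deg]
    if not all(math.isfinite(a) for a in angles_deg):
        raise ValueError("angles must be finite")
    if all(a == 0.0 for a in angles_deg):
        out_vox = phantom.voxels.copy()
        out_mask = phantom.breast_mask.copy()
    else:
        r = _rotation_matrix(angles_deg)
        if center == "centroid":
            c = np.array(np.nonzero(phantom.breast_mask), dtype=float).mean(axis=1)
        else:
            c = (np.asarray(phantom.shape, dtype=float) - 1.0) / 2.0
        rinv = r.T
        offset = c - rinv @ c
        out_vox = ndimage.affine_transform(
            phantom.voxels, rinv, offset=offset, order=0, cval=AIR_INDEX, prefilter=False,
            output=np.uint8,
        )
        out_mask = (
            ndimage.affine_transform(
                phantom.breast_mask.astype(np.uint8), rinv, offset=offset, order=0, cval=0,
                prefilter=False,
            )
            > 0
        )
    prov = dict(phantom.provenance)
    prov["rotation_deg"] = list(angles_deg)
    return Phantom(
        voxels=out_vox,
        material_table=dict(phantom.material_table),
        breast_mask=out_mask,
        voxel_mm=phantom.voxel_mm,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Serialization: raw uint8 volume + text sidecar
# ---------------------------------------------------------------------------


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    """Write ``<path>.raw`` (uint8, x fastest, then y, then z) plus ``<path>.json``.

    The sidecar records dimensions, voxel size, the material table and
    provenance so the pair is a lossless, self-describing container that a
    downstream projection tool can ingest.
    """
    path = Path(path)
    path = path.with_suffix("") if path.suffix in {".raw", ".json"} else path
    nx, ny, nz = phantom.shape
    phantom.voxels.transpose(2, 1, 0).tofile(path.with_suffix(".raw"))
    mask_packed = np.packbits(phantom.breast_mask.transpose(2, 1, 0).astype(np.uint8))
    mask_packed.tofile(path.with_suffix(".mask"))
    sidecar = {
        "shape_xyz": [nx, ny, nz],
        "voxel_mm": phantom.voxel_mm,
        "dtype": "uint8",
        "order": "x-fastest",
        "material_table": {str(k): v for k, v in phantom.material_table.items()},
        "provenance": phantom.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    path = path.with_suffix("") if path.suffix in {".raw", ".json"} else path
    sidecar = json.loads(path.with_suffix(".json").read_text())
    nx, ny, nz = sidecar["shape_xyz"]
    raw = np.fromfile(path.with_suffix(".raw"), dtype=np.uint8)
    if raw.size != nx * ny * nz:
        raise ValueError(
            f"raw file holds {raw.size} voxels but sidecar declares {nx}x{ny}x{nz} = {nx * ny * nz}"
        )
    vox = raw.reshape(nz, ny, nx).transpose(2, 1, 0)
    packed = np.fromfile(path.with_suffix(".mask"), dtype=np.uint8)
    mask = np.unpackbits(packed, count=nx * ny * nz).reshape(nz, ny, nx).transpose(2, 1, 0).astype(bool)
    return Phantom(
        voxels=vox.copy(),
        material_table={int(k): float(v) for k, v in sidecar["material_table"].items()},
        breast_mask=mask.copy(),
        voxel_mm=float(sidecar["voxel_mm"]),
        provenance=sidecar.get("provenance", {}),
    )
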