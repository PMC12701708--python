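# Methods

This note documents the models implemented in `breastvit`, their
assumptions, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical choices that
affect reproducibility.

## Population model

### Variables and margins

One record per woman per screening round: breast volume *V* (cm³), dense
volume *V_d* (cm³), age *A* (years), annualized change in breast volume ΔV
(cm³/yr) and annualized change in volumetric breast density ΔVBD
(pp/yr). The delta variables are annualized — the raw between-screen change
divided by the elapsed time — so cohorts with heterogeneous screening
intervals are comparable.

Margins are estimated nonparametrically: a Gaussian-kernel CDF with
Silverman's bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)`, evaluated on a
1024-point grid spanning the data range ± 5 bandwidths, with monotone linear
interpolation for both directions. *V* and *V_d* are log-transformed first
(strictly positive, right-skewed), which also guarantees positive sampled
volumes after back-transformation. Pseudo-observations are rescaled by
n/(n+1) to keep them off the {0, 1} boundary.

### Copula estimation

Dependence is a Student-t copula (ρ̂, ν̂), chosen because screening data show
joint tail behavior a Gaussian copula underestimates. Estimation is
pseudo-maximum likelihood in two steps:

1. **ρ̂ by rank inversion.** Pairwise Kendall tau-b, then ρ = sin(πτ/2)
   (exact for elliptical copulas), then projection onto the correlation
   matrices by eigenvalue clipping at 1e-6 and diagonal rescaling. This is
   robust to the margins and reproducible with no optimizer in the loop.
2. **ν̂ by profile likelihood.** With ρ̂ and the margins fixed, the t-copula
   log-density is maximized over ν ∈ (2.05, 100] by bounded scalar
   minimization (`xatol` 1e-3). The bounds keep variance finite and the
   search deterministic.

Validation identities used by the tests: sampling then computing tau
recovers (2/π) arcsin(ρ̂ᵢⱼ) for every pair; fit → sample → fit round-trips
ρ̂ within ±0.03 at n = 25 188; refitting a synthetic cohort generated from
the published parameters recovers ρ(V, V_d) = 0.64 within ±0.02 and ν within
a few percent.

Age-stratified fits use a ± 0.5-year window around each target age; the
record-count floor is configurable because half-year strata near the age
boundaries of a screening program are sparse.

Goodness of fit samples `n_replicates` virtual populations of the cohort's
size and reports marginal means/sds (replicate-averaged) and, per variable
pair, the real tau against the replicate mean with a 2.5–97.5 percentile
interval. Percentile intervals are the minimal assumption given no
distributional claim about tau across replicates.

### Synthetic cohort generator

The fixture emulates a large digital-mammography screening population by its
published summary statistics: lognormal margins for *V* (848 ± 495 cm³) and
*V_d* (74 ± 42 cm³) moment-matched on the natural scale (σ² = ln(1 +
(sd/mean)²), μ = ln mean − σ²/2), a normal truncated to [40, 74] for age
(53 ± 10 before truncation), normals for ΔV (14 ± 95 cm³/yr) and ΔVBD
(0.5 ± 11 pp/yr), and t-copula dependence with the published 5×5 correlation
matrix and ν = 16.44. Units: ΔVBD is in percentage points per year (the
variable is a density change; a cm³ label for it would be dimensionally
inconsistent with the other published values).

What it does **not** emulate: the administrative pile-up of first screens at
the entry age (available as an optional mixture weight, off by default,
because it is an artifact of invitation logistics, not biology); scanner mix
and screening-interval logistics; exclusion workflows; and any real-data
deviation from the parametric margin families. Passing tests therefore show
that the estimators recover a *known* data-generating process at clinical
sample sizes — not that real screening data follow lognormal/t-copula form.
The rare joint event V_d > V is clipped to V_d = V for physical consistency.

## Phantom model

### Texture

Classic lattice gradient noise: seeded random unit gradient vectors on
lattice nodes (drawn per (seed, octave), not a hash permutation, so any grid
size works without wraparound), quintic fade 6t⁵ − 15t⁴ + 10t³, dot-product
interpolation. Octaves are summed with lacunarity 2.0 and persistence 0.5
(4 octaves for the coarse block) and normalized by the geometric amplitude
sum; values map affinely to [0, 1] using the theoretical single-octave bound
±√3/2 rather than per-volume min/max, so a threshold means the same thing in
every phantom — the property that makes the SF calibration transferable
across seeds.

Two default texture blocks make up a breast: a coarse glandular block
(base frequency 12 lattice cells along the longest grid edge ⇒ coarsest
structures ≈ 18 mm on a 220 mm grid, the scale of glandular lobes) and a
fine connective block (frequency 32, 3 octaves). Frequency 12 was chosen
over much coarser settings because a breast must contain enough independent
texture cells for its density to be reproducible across seeds; the measured
seed-to-seed VBD sd at the default grid is ≈ 0.15 pp. Block count and all
noise parameters are configuration.

### Outline and assembly

The breast outline is a half-ellipsoid with a flat chest-wall face at y = 0,
generalized by a superelliptic taper: the cross-section at height y is an
ellipse scaled by (1 − (y/b)^p)^(1/p), with p = 3 by default (p = 2 is the
exact half-ellipsoid). The blunter p = 3 profile lets the published mean
breast volume (848 cm³) fit the standard 2200×1200×600 voxel grid at 0.1 mm,
which a pure half-ellipsoid cannot (its maximum is ≈ 829 cm³ there). The
solver sizes the outline analytically and applies up to three discrete
corrections; the voxel volume matches the target within 1% (enforced).

Assembly labels inside-breast voxels glandular where any block's field
exceeds its effective threshold (later blocks take precedence), else
adipose; outside is air (index 0). The material table maps indices to
glandular weights: adipose = 0, a 0.1-step ramp (indices 2–11) to pure
glandular = 1, lesion = index 12. Weights are configuration, since the
attenuation dictionary of the downstream projection tool defines what each
index must mean. VBD% = 100 Σ w_g / N over breast voxels; air is excluded
from both sums.

Noise evaluation accepts z-slabs with identical output, so full-scale grids
(1.6·10⁹ voxels) can be assembled tile-wise; tests and the acceptance script
use the 220×120×60 grid at 1 mm, whose calibration behaves consistently.

### Density calibration

For each scaling factor in the level list, `n_phantoms` independently seeded
phantoms are built and measured (the noise fields are generated once per
seed and re-thresholded per SF — exact, because thresholding is
deterministic). The means are fitted by a quadratic in log-density,
VBD(SF) = exp(q₀ + q₁SF + q₂SF²), which is near-linear for
threshold-on-noise data and strictly monotone over the calibrated range
(checked; fitting fails loudly otherwise). Inversion is by bisection at 1e-6;
targets are accepted only inside the calibrated density range (no
extrapolation), with targets marginally past a curve endpoint — possible
because fit residuals can leave a level mean just outside the curve's span —
clamped to that endpoint's SF. Default levels (0.93, 0.96, 0.99, 1.02, 1.05)
span ≈ 3–26% VBD on the default grid, covering both the screening
population's density band and the Method A trajectory (14/9/6%).

### Repositioning and serialization

Rotation is rigid, about the breast-mask centroid by default (grid center
optionally), with nearest-neighbor resampling so no new tissue indices are
invented; rotation-matrix entries within 1e-12 of {0, ±1} are snapped so
90°-multiples permute voxels exactly. Out-of-grid voxels become air. Small
random angles (default ±5°) can be drawn from a seed to emulate
repositioning between visits.

Phantoms serialize as raw uint8 (x fastest, then y, then z) plus a JSON
sidecar with dimensions, voxel size, material table and provenance (seeds,
SF, insertions, rotations). Loading validates the raw size against the
sidecar.

## Lesions

Surface model: r(θ, φ) = (d/2)(1 + a·n(direction)) with n a single-octave
noise field (frequency 3) on the unit sphere and amplitude a = 0.1. Because
n depends only on direction, regrowth at a new diameter preserves the margin
pattern; because |a·n| ≤ 0.1, the axis extent stays within 10% of the
declared diameter by construction (a = 0 gives an exact voxelized sphere).
Composition methods: (1) homogeneous lesion index; (2) host glandular
weights multiplied by an enhancement factor (default 1.5, clamped to weight
1.0) — heterogeneity inherited from the phantom; (3) additionally an
interior fractal texture evaluated in the size-normalized frame, combined as
max(enhanced weight, interior value) and quantized onto the material ramp.

Growth: d(t) = d₀(1 + t/TDT), linear in diameter, doubling the *diameter*
per TDT — the convention of the clinical worked example (5 → 10 mm over
282 days, ≈ 18 mm at 730 days). The term "volume doubling time" literally
implies d·2^(t/(3·TDT)); that strict mode is available via
`volume_doubling=True`. TDT population draws use a normal truncated to the
observed clinical range 46–749 days (mean 282); the sd (150 d) is a
placeholder for the unpublished distribution shape and is pluggable.
Tumor growth is independent of the host's age. Years convert to days at
365 d/yr so that "two years" equals the 730-day example horizon.

## Lesion insertion

Quadrants are defined by the horizontal (superior/inferior) and vertical
(medial/lateral) planes through the nipple; a laterality flag decides which
x-side is "outer", and plane-boundary voxels go to the upper/outer side so
the labels partition the breast. The published quadrant frequencies sum to
92.5%; they are renormalized over the four quadrants (the residual
plausibly corresponds to central/retroareolar lesions, which this model does
not place).

The "density follows lesion position" assumption is operationalized
*locally*: within the sampled quadrant, the center-voxel probability is
proportional to the voxel's glandular weight plus a floor ε = 0.01 (so fully
adipose quadrants remain possible). Whether the clinical relationship is
with local or quadrant-aggregate density is ambiguous; local weighting is
the most direct reading and is flagged here.

Centers are restricted to an interior mask: the Euclidean distance transform
of the breast mask thresholded at the largest distance whose voxel count is
≤ 90% of the breast volume (uniform inward erosion; ties resolved upward so
the count never exceeds the fraction). The lesion *body* may extend beyond
the interior mask but never beyond the breast; automatic insertion retries
up to 10 times on a failed draw, manual insertion fails loudly.

## Temporal evolution

* **Method A** (population curves): VBD(a) = 10.14 · exp(r(a − 53)) with
  r = ln((10.14 − 0.25)/10.14) ≈ −0.02496/yr — the exponential through the
  anchor and the anchor-plus-one-year point; V(a) = 848 + 14(a − 53) cm³.
  VBD is strictly decreasing and volume strictly increasing on [40, 74].
* **Method B** (piecewise rates): year-by-year integration where the year
  [a, a+1) uses the rates of the age group containing integer a (a fixed
  convention; the groups are 40–44: −0.27 pp, +16.64 cm³; 45–54: −0.38,
  +18.43; 55–64: −0.15, +11.68; 65–74: −0.028, +0.60 per year). The density
  decrement is a re-anchored exponential whose whole-year effect equals
  adding the pp/yr rate exactly (fractional years take the matching
  fractional power), so the series is continuous at group boundaries.
  The cumulative 40 → 74 volume gain under these rates is 389.7 cm³.
* **Method C** (individual draw): one (ΔV, ΔVBD) pair from the fitted
  copula, applied over a single inter-screen interval. Timelines with more
  than two evaluation ages reject Method C: repeated independent draws
  accumulate random variation instead of following the population trend.

A timeline fixes one phantom seed per woman and varies only the outline
volume (shape) and SF (composition) per age. Because raising SF removes
structures on the same noise field, the age-t₂ glandular voxel set is a
subset of the age-t₁ set whenever density declines — involution on
registered anatomy.

## Pipeline, configuration, previews

`run_pipeline` executes cohort → copula fit → calibration → per-woman
timelines → per-age phantom builds (optional lesion insertion and small
rotations) from one `RunConfig`; every stage seed derives from the config
seed and is recorded in the manifest, so an archived config reproduces a run
bit-exactly. The ray-sum preview is an orthographic sum of glandular weights
scaled to 8-bit grayscale — deliberately naive plumbing for visual checks,
not an imaging model.

## Problem sizes and limitations

Tests and the acceptance script use the desk-scale 220×120×60 grid at 1 mm
(the full-resolution default, 2200×1200×600 at 0.1 mm, is supported via
slab-wise evaluation but is not exercised end-to-end in the suite), cohorts
of n = 25 188 with 20 tau replicates and 100 marginal replicates, and a
5-level × 10-phantom calibration. Known limitations: no skin layer, no
compression, no microcalcifications or architectural distortions, no
BI-RADS category replication, isotropic noise (no ductal anisotropy
converging on the nipple), and no conditional sampling beyond age
stratification.
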