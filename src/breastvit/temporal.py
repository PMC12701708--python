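"""Temporal evolution of breast density, breast volume and tumor size.

Three methods evolve a virtual woman across screening ages (40–74 years):

* **Method A** — single population-level curves: volumetric breast density
  follows an exponential through the cohort anchor (53 yr, 10.14%) with an
  annual change of −0.25 percentage points, i.e. rate
  ``r = ln((10.14 − 0.25) / 10.14)`` per year; breast volume is linear
  through (53 yr, 848 cm³) with +14 cm³/yr.
* **Method B** — piecewise (age-group) rates applied stepwise year by year:
  each age group has its own density change (pp/yr) and volume change
  (cm³/yr); the density decrement is a re-anchored exponential per year,
  which for whole years equals subtracting the group's pp/yr rate.
* **Method C** — an individual draw of (Δvolume, Δdensity) from the fitted
  t-copula, appropriate for exactly two consecutive screening rounds; for
  longer horizons random individual draws accumulate variance, so Methods
  A/B are required instead.

A :class:`Timeline` couples the per-age density/volume targets with a fixed
phantom seed and per-age threshold scaling factors, so successive phantoms
share the same noise realization and density decline is realized purely by
raising the threshold — glandular structures only ever disappear, emulating
tissue involution on spatially registered anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lesion import GrowthModel, grown_diameter
from .population import TCopulaResults
from .texture import DensityCalibration, sf_for_density

__all__ = [
    "AGE_RANGE",
    "DAYS_PER_YEAR",
    "TrajectoryParamsA",
    "AgeGroupRates",
    "DEFAULT_AGE_GROUP_RATES",
    "Timeline",
    "vbd_method_A",
    "volume_method_A",
    "trajectory_method_B",
    "deltas_method_C",
    "build_timeline",
]

AGE_RANGE = (40.0, 74.0)
#: 365 so that "two years" equals the 730-day horizon of the worked example
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class TrajectoryParamsA:
    """Anchors of the Method A population curves."""

    anchor_age: float = 53.0
    anchor_vbd: float = 10.14  # %
    annual_vbd_change: float = -0.25  # percentage points per year
    anchor_volume: float = 848.0  # cm^3
    annual_volume_change: float = 14.0  # cm^3 per year

    def __post_init__(self) -> None:
        if self.anchor_vbd <= 0 or self.anchor_volume <= 0:
            raise ValueError("anchors must be positive")
        if self.anchor_vbd + self.annual_vbd_change <= 0:
            raise ValueError("annual VBD change would drive density non-positive within a year")

    @property
    def vbd_rate(self) -> float:
        """Exponential rate per year from the two anchor points."""
        return math.log((self.anchor_vbd + self.annual_vbd_change) / self.anchor_vbd)


@dataclass(frozen=True)
class AgeGroupRates:
    """Piecewise annual rates: (age_lo, age_hi, vbd pp/yr, volume cm^3/yr)."""

    groups: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        gs = sorted(self.groups)
        if not gs:
            raise ValueError("at least one age group required")
        for (lo, hi, *_), nxt in zip(gs, gs[1:]):
            if hi + 1 != nxt[0]:
                raise ValueError("age groups must be contiguous and non-overlapping")

    def rates_at(self, age: float) -> tuple[float, float]:
        """(vbd pp/yr, volume cm^3/yr) of the group containing integer age floor(age)."""
        a = math.floor(age)
        for lo, hi, dv, dvol in self.groups:
            if lo <= a <= hi:
                return dv, dvol
        raise ValueError(f"age {age} outside the covered groups")


#: published age-group rates: VBD change (pp/yr) and volume change (cm^3/yr)
DEFAULT_AGE_GROUP_RATES = AgeGroupRates(
    groups=(
        (40.0, 44.0, -0.27, 16.64),
        (45.0, 54.0, -0.38, 18.43),
        (55.0, 64.0, -0.15, 11.68),
        (65.0, 74.0, -0.028, 0.60),
    )
)


def _check_age(age: float) -> None:
    if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        raise ValueError(f"age {age} outside the screening model range {AGE_RANGE}")


def vbd_method_A(p: TrajectoryParamsA, age: float) -> float:
    """Exponential population density curve: anchor_vbd * exp(r * (age - anchor_age))."""
    _check_age(age)
    return p.anchor_vbd * math.exp(p.vbd_rate * (age - p.anchor_age))


def volume_method_A(p: TrajectoryParamsA, age: float) -> float:
    """Linear population volume curve through the anchor."""
    _check_age(age)
    return p.anchor_volume + p.annual_volume_change * (age - p.anchor_age)


def trajectory_method_B(
    start_age: float,
    start_vbd: float,
    start_volume: float,
    rates: AgeGroupRates = DEFAULT_AGE_GROUP_RATES,
    ages: Sequence[float] = (),
) -> tuple[list[float], list[float]]:
    """Stepwise integration with age-group rates, evaluated at the requested ages.

    Within each year the group is chosen by the current integer age; density
    is updated by a re-anchored exponential whose full-year effect equals
    adding the group's pp/yr rate (fractional years use the matching
    fractional power), and volume accrues linearly.
    """
    ages = sorted(float(a) for a in ages)
    if not ages:
        return [], []
    if start_age > ages[0]:
        raise ValueError("start_age must not exceed the first evaluation age")
    _check_age(start_age)
    for a in ages:
        _check_age(a)
    vbd, vol, t = float(start_vbd), float(start_volume), float(start_age)
    out_v, out_V = [], []
    for target in ages:
        while t < target - 1e-12:
            step_end = min(math.floor(t) + 1.0, target)
            dt = step_end - t
            pp_rate, vol_rate = rates.rates_at(t)
            if vbd + pp_rate <= 0:
                raise ValueError(f"VBD would become non-positive near age {t:.1f}")
            vbd *= ((vbd + pp_rate) / vbd) ** dt
            vol += vol_rate * dt
            t = step_end
        out_v.append(vbd)
        out_V.append(vol)
    return out_v, out_V


def deltas_method_C(
    results: TCopulaResults,
    seed: int | np.random.Generator = 0,
    woman=None,
) -> tuple[float, float]:
    """One individual draw of (Δvolume cm³/yr, Δvbd pp/yr) from the fitted copula.

    The draw is from the joint fit, not conditioned on ``woman`` (kept for
    provenance); it applies to a single inter-screen interval only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row = results.sample(1, rng).iloc[0]
    return float(row.dvolume_cm3_per_yr), float(row.dvbd_pp_per_yr)


@dataclass
class Timeline:
    """Per-age build schedule for one virtual woman.

    The phantom seed is constant across ages: density change is realized by
    the per-age scaling factors on the *same* noise realization (involution),
    and volume change by resizing the outline.
    """

    woman_id: str
    ages: tuple[float, ...]
    vbd_series: tuple[float, ...]  # % per age
    volume_series: tuple[float, ...]  # cm^3 per age
    method: str
    phantom_seed: int
    sf_series: tuple[float, ...] | None = None
    tumor_series: tuple[float, ...] | None = None  # diameter mm per age
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = self.ages
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        for a in ages:
            _check_age(a)
        if len(self.vbd_series) != len(ages) or len(self.volume_series) != len(ages):
            raise ValueError("series lengths must match the number of ages")

    def to_frame(self):
        import pandas as pd

        data = {
            "age": self.ages,
            "target_vbd_pct": self.vbd_series,
            "volume_cm3": self.volume_series,
        }
        if self.sf_series is not None:
            data["sf"] = self.sf_series
        if self.tumor_series is not None:
            data["tumor_mm"] = self.tumor_series
        return pd.DataFrame(data)


def build_timeline(
    woman_id: str,
    ages: Sequence[float],
    method: str = "A",
    calibration: DensityCalibration | None = None,
    growth: GrowthModel | None = None,
    *,
    params_a: TrajectoryParamsA = TrajectoryParamsA(),
    rates: AgeGroupRates = DEFAULT_AGE_GROUP_RATES,
    copula: TCopulaResults | None = None,
    start_vbd: float | None = None,
    start_volume: float | None = None,
    phantom_seed: int = 0,
    seed: int = 0,
) -> Timeline:
    """Compute the per-age density/volume/tumor schedule for one woman.

    Method A needs only the population anchors; Method B starts from the
    woman's own (vbd, volume) at the first age; Method C draws her
    individual annual deltas from the fitted copula and is restricted to two
    evaluation ages.  If a density calibration is given, the per-age
    threshold scaling factors are interpolated from it.
    """
    ages = tuple(sorted(float(a) for a in ages))
    method = method.upper()
    if method == "A":
        vbd = [vbd_method_A(params_a, a) for a in ages]
        vol = [volume_method_A(params_a, a) for a in ages]
    elif method == "B":
        if start_vbd is None or start_volume is None:
            raise ValueError("Method B needs the woman's start_vbd and start_volume")
        vbd, vol = trajectory_method_B(ages[0], start_vbd, start_volume, rates, ages)
    elif method == "C":
        if len(ages) > 2:
            raise ValueError(
                "Method C samples one inter-screen change and supports at most two "
                "time points; use Method A or B for longitudinal simulation"
            )
        if copula is None or start_vbd is None or start_volume is None:
            raise ValueError("Method C needs a fitted copula and the woman's start state")
        dvol, dvbd = deltas_method_C(copula, seed)
        vbd, vol = [start_vbd], [start_volume]
        if len(ages) == 2:
            dt = ages[1] - ages[0]
            vbd.append(start_vbd + dvbd * dt)
            vol.append(start_volume + dvol * dt)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'A', 'B' or 'C'")

    sf = None
    if calibration is not None:
        sf = tuple(sf_for_density(calibration, v) for v in vbd)
    tumor = None
    if growth is not None:
        tumor = tuple(
            grown_diameter(growth, (a - ages[0]) * DAYS_PER_YEAR) for a in ages
        )
    return Timeline(
        woman_id=woman_id,
        ages=ages,
        vbd_series=tuple(vbd),
        volume_series=tuple(vol),
        method=method,
        phantom_seed=int(phantom_seed),
        sf_series=sf,
        tumor_series=tumor,
        meta={"seed": int(seed)},
    )
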