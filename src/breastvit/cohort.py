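"""Synthetic screening cohorts with the dependence structure of a real DM population.

Generates tabular cohorts (one row per woman: age, breast volume, dense
volume, and the annualized between-screen changes in volume and density)
whose marginal moments and t-copula dependence match published values from a
large Swedish digital-mammography screening population.  This makes every
downstream stage — copula fitting, phantom building, temporal simulation —
testable without access to the original clinical data.

Marginal families are the simplest ones consistent with the printed moments
and sign constraints: lognormal for the two volumes (strictly positive,
right-skewed; moment-matched so the *natural-scale* mean and SD are
reproduced), a truncated normal on [40, 74] for age, and normals for the two
delta variables, which take both signs.  Dependence is induced by drawing
uniforms from a Student-t copula and inverting each margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .population import COLUMNS, ScreeningRecord, frame_to_records, sample_t_copula

__all__ = [
    "FixtureSpec",
    "DEFAULT_MARGINALS",
    "DEFAULT_RHO",
    "DEFAULT_NU",
    "generate_cohort",
    "generate_cohort_frame",
    "lognormal_params",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: published real-world marginal moments (mean, sd) on the natural scale
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "breast_volume_cm3": (848.0, 495.0),
    "dense_volume_cm3": (74.0, 42.0),
    "age": (53.0, 10.0),
    "dvolume_cm3_per_yr": (14.0, 95.0),
    "dvbd_pp_per_yr": (0.5, 11.0),
}

#: published t-copula correlation matrix, variable order:
#: breast volume, dense volume, age, delta volume, delta density
DEFAULT_RHO = np.array(
    [
        [1.00, 0.64, 0.18, -0.05, 0.07],
        [0.64, 1.00, -0.16, -0.04, -0.20],
        [0.18, -0.16, 1.00, -0.07, 0.02],
        [-0.05, -0.04, -0.07, 1.00, -0.52],
        [0.07, -0.20, 0.02, -0.52, 1.00],
    ]
)

#: published degrees of freedom of the fitted t-copula
DEFAULT_NU = 16.44


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) so that exp(N(mu, sigma^2)) has the given mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moment matching needs positive mean and sd")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort.

    ``marginal_params`` gives per-variable (mean, sd) on the natural scale;
    ``rho``/``nu`` parameterize the t-copula; ``age_range`` bounds the
    truncated-normal age margin.  ``age40_spike`` optionally mixes in a point
    mass at the lower age bound, emulating the administrative pile-up of
    first-screen invitations at the entry age; it is off by default.
    """

    n: int
    seed: int = 0
    marginal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    rho: np.ndarray = field(default_factory=lambda: DEFAULT_RHO.copy())
    nu: float = DEFAULT_NU
    age_range: tuple[float, float] = (40.0, 74.0)
    age40_spike: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.nu <= 2:
            raise ValueError("degrees of freedom nu must exceed 2")
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (5, 5) or not np.allclose(rho, rho.T) or not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must be a symmetric 5x5 matrix with unit diagonal")
        try:
            np.linalg.cholesky(rho)
        except np.linalg.LinAlgError as err:
            raise ValueError("rho must be positive definite") from err
        for col in ("breast_volume_cm3", "dense_volume_cm3"):
            if self.marginal_params[col][1] <= 0:
                raise ValueError(f"{col} sd must be positive")
        if not 0.0 <= self.age40_spike < 1.0:
            raise ValueError("age40_spike must be in [0, 1)")


def generate_cohort_frame(spec: FixtureSpec) -> pd.DataFrame:
    """Synthetic cohort as a DataFrame in the canonical column order."""
    rng = np.random.default_rng(spec.seed)
    u = sample_t_copula(np.asarray(spec.rho, dtype=float), spec.nu, spec.n, rng)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    out: dict[str, np.ndarray] = {}

    lo, hi = spec.age_range
    mean_a, sd_a = spec.marginal_params["age"]
    out["age"] = stats.truncnorm.ppf(
        u[:, 2], (lo - mean_a) / sd_a, (hi - mean_a) / sd_a, loc=mean_a, scale=sd_a
    )
    if spec.age40_spike > 0 and spec.n:
        spike = rng.random(spec.n) < spec.age40_spike
        out["age"] = np.where(spike, lo, out["age"])

    for k, col in ((0, "breast_volume_cm3"), (1, "dense_volume_cm3")):
        mu, sigma = lognormal_params(*spec.marginal_params[col])
        out[col] = np.exp(mu + sigma * stats.norm.ppf(u[:, k]))
    for k, col in ((3, "dvolume_cm3_per_yr"), (4, "dvbd_pp_per_yr")):
        mean, sd = spec.marginal_params[col]
        out[col] = stats.norm.ppf(u[:, k], loc=mean, scale=sd)

    # physical constraint: dense tissue cannot exceed the whole breast
    # (vanishingly rare under the matched moments, but enforce it)
    out["dense_volume_cm3"] = np.minimum(out["dense_volume_cm3"], out["breast_volume_cm3"])
    return pd.DataFrame(out, columns=list(COLUMNS))


def generate_cohort(spec: FixtureSpec) -> list[ScreeningRecord]:
    """Synthetic cohort as a list of :class:`ScreeningRecord`."""
    return frame_to_records(generate_cohort_frame(spec))


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.loc[:, list(COLUMNS)].to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns {missing}")
    return frame.loc[:, list(COLUMNS)]
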