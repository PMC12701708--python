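"""t-copula population modeling for screening cohorts.

Five variables describe each woman at a screening round: breast volume
(cm^3), dense volume (cm^3), age (years), and the annualized changes in
breast volume (cm^3/yr) and in volumetric breast density (percentage
points/yr) between two consecutive screens.  Their joint distribution is
modeled semi-parametrically: kernel-smoothed marginal CDFs (volumes on the
log scale) map each variable onto (0, 1), and a Student-t copula — a
correlation matrix ``rho`` plus degrees of freedom ``nu`` — captures the
dependence, including the tail dependence visible in real screening data.

The public surface follows the Model/Results convention: build a
:class:`TCopulaPopulationModel` from a cohort DataFrame, call ``fit()`` to
obtain a :class:`TCopulaResults` carrying ``rho``, ``nu`` and the margins,
then ``sample()`` virtual populations or run ``goodness_of_fit()``.
Estimation is pseudo-maximum likelihood: ``rho`` by Kendall-tau inversion
(``rho = sin(pi * tau / 2)`` for elliptical copulas) with a nearest
positive-definite projection, ``nu`` by profile likelihood of the copula
density with the margins held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "COLUMNS",
    "LOG_COLUMNS",
    "ScreeningRecord",
    "KernelMargin",
    "TCopulaPopulationModel",
    "TCopulaResults",
    "GofReport",
    "fit_copula",
    "sample_population",
    "fit_age_stratified",
    "kendall_tau",
    "copula_implied_tau",
    "goodness_of_fit",
    "sample_t_copula",
    "nearest_correlation",
]

#: canonical cohort schema (CSV header order)
COLUMNS = (
    "age",
    "breast_volume_cm3",
    "dense_volume_cm3",
    "dvolume_cm3_per_yr",
    "dvbd_pp_per_yr",
)
#: strictly positive, right-skewed variables fitted on the log scale
LOG_COLUMNS = ("breast_volume_cm3", "dense_volume_cm3")

MIN_RECORDS = 50


@dataclass(frozen=True)
class ScreeningRecord:
    """One woman's five copula variables at a screening round."""

    age: float
    breast_volume: float  # cm^3
    dense_volume: float  # cm^3
    delta_volume: float  # cm^3 per year, annualized between-screen change
    delta_vbd: float  # percentage points per year, annualized

    def __post_init__(self) -> None:
        if self.breast_volume <= 0:
            raise ValueError("breast_volume must be positive")
        if not 0 <= self.dense_volume <= self.breast_volume:
            raise ValueError("dense_volume must be in [0, breast_volume]")


def records_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [r.age for r in records],
            "breast_volume_cm3": [r.breast_volume for r in records],
            "dense_volume_cm3": [r.dense_volume for r in records],
            "dvolume_cm3_per_yr": [r.delta_volume for r in records],
            "dvbd_pp_per_yr": [r.delta_vbd for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[ScreeningRecord]:
    return [
        ScreeningRecord(
            age=row.age,
            breast_volume=row.breast_volume_cm3,
            dense_volume=row.dense_volume_cm3,
            delta_volume=row.dvolume_cm3_per_yr,
            delta_vbd=row.dvbd_pp_per_yr,
        )
        for row in frame.itertuples(index=False)
    ]


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns {missing}")
        return data.loc[:, list(COLUMNS)].reset_index(drop=True)
    return records_to_frame(list(data))


# ---------------------------------------------------------------------------
# Rank statistics and elliptical-copula identities
# ---------------------------------------------------------------------------


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.kendalltau(x, y).statistic)


def copula_implied_tau(rho_ij: float) -> float:
    """Population Kendall tau implied by an elliptical-copula correlation.

    ``tau = (2/pi) * arcsin(rho)`` holds for every elliptical copula
    (Gaussian and Student-t alike), which makes this the analytic oracle for
    both fitting and sampling.
    """
    if not -1.0 < rho_ij < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    return float(2.0 / math.pi * math.asin(rho_ij))


def nearest_correlation(m: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the correlation matrices (eigenvalue clipping)."""
    sym = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def sample_t_copula(rho: np.ndarray, nu: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` uniform(0,1)^d vectors with t-copula dependence (rho, nu)."""
    rho = np.asarray(rho, dtype=float)
    d = rho.shape[0]
    if n == 0:
        return np.empty((0, d))
    chol = np.linalg.cholesky(rho)
    z = rng.standard_normal((n, d)) @ chol.T
    w = rng.chisquare(nu, size=n) / nu
    x = z / np.sqrt(w)[:, None]
    return stats.t.cdf(x, df=nu)


# ---------------------------------------------------------------------------
# Kernel-smoothed margins
# ---------------------------------------------------------------------------


@dataclass
class KernelMargin:
    """Invertible kernel-smoothed CDF estimate of one variable.

    A Gaussian kernel with Silverman's bandwidth is evaluated on a dense grid
    over the (possibly log-transformed) data range extended by five
    bandwidths; monotone linear interpolation gives both ``cdf`` and ``ppf``.
    """

    grid: np.ndarray  # transformed scale
    cdf_grid: np.ndarray
    log: bool
    bandwidth: float

    @classmethod
    def fit(cls, x: np.ndarray, *, log: bool, n_grid: int = 1024) -> "KernelMargin":
        x = np.asarray(x, dtype=float)
        t = np.log(x) if log else x
        sd = t.std(ddof=1)
        if sd == 0:
            raise ValueError("constant variable")
        iqr = np.subtract(*np.percentile(t, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * t.size ** (-0.2)
        grid = np.linspace(t.min() - 5 * h, t.max() + 5 * h, n_grid)
        cdf = np.zeros(n_grid)
        # chunk the kernel sum to bound memory at ~n * 64 doubles
        for j0 in range(0, n_grid, 64):
            block = grid[j0 : j0 + 64]
            cdf[j0 : j0 + 64] = stats.norm.cdf((block[None, :] - t[:, None]) / h).mean(axis=0)
        return cls(grid=grid, cdf_grid=cdf, log=log, bandwidth=float(h))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        t = np.log(np.asarray(x, dtype=float)) if self.log else np.asarray(x, dtype=float)
        return np.interp(t, self.grid, self.cdf_grid)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(np.asarray(u, dtype=float), self.cdf_grid[0], self.cdf_grid[-1])
        t = np.interp(u, self.cdf_grid, self.grid)
        return np.exp(t) if self.log else t


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class TCopulaPopulationModel:
    """Semi-parametric population model of a screening cohort.

    Parameters
    ----------
    data
        Cohort DataFrame with the canonical columns, or a sequence of
        :class:`ScreeningRecord`.
    log_columns
        Variables log-transformed before margin estimation (default: the two
        volume variables, which are strictly positive and right-skewed).
    """

    def __init__(self, data, log_columns: Sequence[str] = LOG_COLUMNS, min_records: int = MIN_RECORDS):
        self.data = _as_frame(data)
        self.log_columns = tuple(log_columns)
        if len(self.data) < max(min_records, 10):
            raise ValueError(
                f"need at least {max(min_records, 10)} records to fit, got {len(self.data)}"
            )
        if self.data.isna().any().any():
            raise ValueError("cohort contains missing values")
        for col in COLUMNS:
            if self.data[col].std(ddof=1) == 0:
                raise ValueError(f"variable {col!r} is constant; cannot estimate its margin")

    @classmethod
    def from_records(cls, records: Sequence[ScreeningRecord], **kw) -> "TCopulaPopulationModel":
        return cls(records_to_frame(list(records)), **kw)

    # -- estimation ---------------------------------------------------------

    def _pseudo_obs(self, margins: dict[str, KernelMargin]) -> np.ndarray:
        n = len(self.data)
        u = np.column_stack([margins[c].cdf(self.data[c].to_numpy()) for c in COLUMNS])
        return np.clip(u * n / (n + 1.0), 1e-10, 1 - 1e-10)

    @staticmethod
    def _profile_loglik(u: np.ndarray, rho: np.ndarray, nu: float) -> float:
        n, d = u.shape
        x = stats.t.ppf(u, df=nu)
        chol = np.linalg.cholesky(rho)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        q = np.square(np.linalg.solve(chol, x.T)).sum(axis=0)
        ll = n * (
            -0.5 * logdet
            + gammaln((nu + d) / 2.0)
            + (d - 1) * gammaln(nu / 2.0)
            - d * gammaln((nu + 1) / 2.0)
        )
        ll -= (nu + d) / 2.0 * np.log1p(q / nu).sum()
        ll += (nu + 1) / 2.0 * np.log1p(x**2 / nu).sum()
        return float(ll)

    def fit(self, nu_bounds: tuple[float, float] = (2.05, 100.0)) -> "TCopulaResults":
        """Pseudo-ML fit: tau-inversion for rho, profile likelihood for nu."""
        margins = {
            c: KernelMargin.fit(self.data[c].to_numpy(), log=c in self.log_columns)
            for c in COLUMNS
        }
        d = len(COLUMNS)
        cols = [self.data[c].to_numpy() for c in COLUMNS]
        tau = np.eye(d)
        for i in range(d):
            for j in range(i + 1, d):
                tau[i, j] = tau[j, i] = kendall_tau(cols[i], cols[j])
        rho = nearest_correlation(np.sin(np.pi * tau / 2.0))
        u = self._pseudo_obs(margins)
        res = minimize_scalar(
            lambda nu: -self._profile_loglik(u, rho, nu),
            bounds=nu_bounds,
            method="bounded",
            options={"xatol": 1e-3},
        )
        return TCopulaResults(
            model=self, rho=rho, nu=float(res.x), margins=margins,
            log_flags={c: c in self.log_columns for c in COLUMNS}, nobs=len(self.data),
        )


@dataclass
class TCopulaResults:
    """Fitted t-copula plus margins; supports sampling, summary and GOF."""

    model: TCopulaPopulationModel | None
    rho: np.ndarray
    nu: float
    margins: dict[str, KernelMargin]
    log_flags: dict[str, bool]
    nobs: int

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (len(COLUMNS), len(COLUMNS)):
            raise ValueError("rho must be 5x5")
        if not np.allclose(rho, rho.T) or not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must be symmetric with unit diagonal")
        np.linalg.cholesky(rho)  # positive definiteness
        if self.nu <= 2:
            raise ValueError("degrees of freedom must exceed 2")
        self.rho = rho

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(COLUMNS), columns=list(COLUMNS))

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
        """Draw a virtual population of ``n`` women (copula draw + margin inversion)."""
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        u = sample_t_copula(self.rho, self.nu, n, rng)
        out = {c: self.margins[c].ppf(u[:, k]) for k, c in enumerate(COLUMNS)}
        frame = pd.DataFrame(out, columns=list(COLUMNS))
        if n:
            # kernel support on the log scale keeps volumes positive; enforce the
            # physical ordering constraint, which smoothing can rarely break
            frame["dense_volume_cm3"] = np.minimum(
                frame["dense_volume_cm3"], frame["breast_volume_cm3"]
            )
        return frame

    def summary(self) -> str:
        lines = [
            "t-copula population model (pseudo-ML)",
            f"  observations: {self.nobs}",
            f"  degrees of freedom nu: {self.nu:.2f}",
            "  copula correlation matrix rho:",
        ]
        lines.append(self.rho_frame().round(3).to_string())
        lines.append("  margins: kernel-smoothed CDF (Gaussian kernel, Silverman bandwidth)")
        for c in COLUMNS:
            tag = " [log scale]" if self.log_flags[c] else ""
            lines.append(f"    {c}: bandwidth {self.margins[c].bandwidth:.4g}{tag}")
        return "\n".join(lines)

    def goodness_of_fit(self, data=None, n_replicates: int = 100, seed: int = 0) -> "GofReport":
        frame = _as_frame(data) if data is not None else self.model.data
        return goodness_of_fit(self, frame, n_replicates=n_replicates, seed=seed)


@dataclass
class GofReport:
    """Bootstrap comparison of a fitted model against the cohort it claims to describe."""

    marginal_table: pd.DataFrame
    tau_table: pd.DataFrame
    n_replicates: int

    def __str__(self) -> str:
        return (
            f"goodness of fit over {self.n_replicates} simulated populations\n\n"
            + self.marginal_table.round(3).to_string(index=False)
            + "\n\n"
            + self.tau_table.round(3).to_string(index=False)
        )

    def n_pairs_inside_ci(self) -> int:
        t = self.tau_table
        return int(((t.tau_real >= t.ci_low) & (t.tau_real <= t.ci_high)).sum())


def goodness_of_fit(
    results: TCopulaResults, records, n_replicates: int = 100, seed: int = 0
) -> GofReport:
    """Sample ``n_replicates`` virtual populations of the cohort's size and compare.

    Marginals: per-variable mean/sd of the real cohort vs the replicate
    average.  Dependence: per-pair real Kendall tau vs the replicate mean with
    a 2.5–97.5 percentile interval.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    frame = _as_frame(records)
    n = len(frame)
    rng = np.random.default_rng(seed)
    d = len(COLUMNS)
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    means = np.zeros((n_replicates, d))
    sds = np.zeros((n_replicates, d))
    taus = np.zeros((n_replicates, len(pairs)))
    for r in range(n_replicates):
        sim = results.sample(n, rng)
        arr = sim.to_numpy()
        means[r] = arr.mean(axis=0)
        sds[r] = arr.std(axis=0, ddof=1)
        for k, (i, j) in enumerate(pairs):
            taus[r, k] = kendall_tau(arr[:, i], arr[:, j])
    real = frame.to_numpy()
    marginal = pd.DataFrame(
        {
            "variable": list(COLUMNS),
            "real_mean": real.mean(axis=0),
            "real_sd": real.std(axis=0, ddof=1),
            "sim_mean": means.mean(axis=0),
            "sim_sd": sds.mean(axis=0),
        }
    )
    tau_real = np.array([kendall_tau(real[:, i], real[:, j]) for i, j in pairs])
    lo, hi = np.percentile(taus, [2.5, 97.5], axis=0)
    tau_table = pd.DataFrame(
        {
            "pair": [f"{COLUMNS[i]};{COLUMNS[j]}" for i, j in pairs],
            "tau_real": tau_real,
            "tau_sim_mean": taus.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    tau_table["delta_tau"] = tau_table.tau_sim_mean - tau_table.tau_real
    return GofReport(marginal_table=marginal, tau_table=tau_table, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Spec-level convenience functions
# ---------------------------------------------------------------------------


def fit_copula(
    records, log_columns: Sequence[str] = LOG_COLUMNS, min_records: int = MIN_RECORDS
) -> TCopulaResults:
    """Fit the t-copula population model to a cohort (records or DataFrame)."""
    return TCopulaPopulationModel(records, log_columns=log_columns, min_records=min_records).fit()


def sample_population(results: TCopulaResults, n: int, seed: int = 0) -> pd.DataFrame:
    return results.sample(n, seed)


def fit_age_stratified(
    records, target_age: float, window: float = 0.5, min_records: int = MIN_RECORDS
) -> TCopulaResults:
    """Fit only to women within ``target_age ± window`` years."""
    if not 40 <= target_age <= 74:
        raise ValueError("target_age must lie in the screening range [40, 74]")
    frame = _as_frame(records)
    sel = frame[(frame.age - target_age).abs() <= window]
    if len(sel) < min_records:
        raise ValueError(
            f"only {len(sel)} records within {window} years of age {target_age}; "
            f"need {min_records}"
        )
    return fit_copula(sel, min_records=min_records)
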