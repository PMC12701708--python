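"""t-copula fitting, sampling, rank statistics and goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from breastvit.cohort import DEFAULT_NU, DEFAULT_RHO, FixtureSpec, generate_cohort_frame
from breastvit.population import (
    COLUMNS,
    KernelMargin,
    ScreeningRecord,
    TCopulaPopulationModel,
    TCopulaResults,
    copula_implied_tau,
    fit_age_stratified,
    fit_copula,
    goodness_of_fit,
    kendall_tau,
    sample_population,
    sample_t_copula,
)


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair count with tie correction (tau-b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    s = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
            s += dx * dy
            tx += dx == 0
            ty += dy == 0
    n0 = n * (n - 1) // 2
    return s / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_perfect_concordance_and_discordance(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        assert kendall_tau(x, y) == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        x = rng.integers(0, 5, size=40)
        y = rng.integers(0, 5, size=40)
        assert kendall_tau(x, y) == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            kendall_tau([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            kendall_tau([1], [1])


class TestImpliedTau:
    @pytest.mark.parametrize(
        "rho, tau",
        [(0.0, 0.0), (-0.52, -0.3481), (0.18, 0.1152), (0.64, 0.4421)],
    )
    def test_closed_form(self, rho, tau):
        assert copula_implied_tau(rho) == pytest.approx(tau, abs=5e-5)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_domain(self, rho):
        with pytest.raises(ValueError):
            copula_implied_tau(rho)


class TestFit:
    def test_too_few_records(self, cohort_frame):
        with pytest.raises(ValueError, match="at least"):
            TCopulaPopulationModel(cohort_frame.head(20))

    def test_constant_variable_named(self, cohort_frame):
        bad = cohort_frame.head(200).copy()
        bad["age"] = 50.0
        with pytest.raises(ValueError, match="age"):
            TCopulaPopulationModel(bad)

    def test_independent_data_fits_near_identity(self):
        frame = generate_cohort_frame(FixtureSpec(n=10_000, seed=13, rho=np.eye(5)))
        res = fit_copula(frame)
        off = res.rho[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_screening_record_validation(self):
        with pytest.raises(ValueError):
            ScreeningRecord(age=50, breast_volume=-1, dense_volume=0, delta_volume=0, delta_vbd=0)
        with pytest.raises(ValueError):
            ScreeningRecord(age=50, breast_volume=100, dense_volume=150, delta_volume=0, delta_vbd=0)

    def test_results_validation(self, fitted):
        bad = fitted.rho.copy()
        bad[0, 1] = 0.5  # breaks symmetry
        with pytest.raises(ValueError):
            TCopulaResults(
                model=None, rho=bad, nu=fitted.nu, margins=fitted.margins,
                log_flags=fitted.log_flags, nobs=fitted.nobs,
            )

    def test_summary_mentions_parameters(self, fitted):
        text = fitted.summary()
        assert "degrees of freedom" in text
        assert "breast_volume_cm3" in text


class TestMargins:
    def test_invertibility_over_data_range(self, cohort_frame, fitted):
        for col in COLUMNS:
            m = fitted.margins[col]
            x = cohort_frame[col].to_numpy()
            back = m.ppf(m.cdf(x))
            scale = np.std(x)
            assert np.max(np.abs(back - x)) < 1e-6 * max(scale, 1.0)

    def test_cdf_monotone(self, fitted):
        m = fitted.margins["breast_volume_cm3"]
        assert (np.diff(m.cdf_grid) > 0).all()

    def test_log_margin_positive_support(self, fitted):
        u = np.linspace(1e-6, 1 - 1e-6, 101)
        assert (fitted.margins["dense_volume_cm3"].ppf(u) > 0).all()

    def test_constant_margin_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            KernelMargin.fit(np.ones(100), log=False)


class TestSampling:
    def test_empty_sample(self, fitted):
        assert len(fitted.sample(0, 1)) == 0

    def test_seeded_reproducibility(self, fitted):
        assert fitted.sample(500, 3).equals(fitted.sample(500, 3))

    def test_volumes_positive(self, fitted):
        sim = fitted.sample(5000, 4)
        assert (sim.breast_volume_cm3 > 0).all()
        assert (sim.dense_volume_cm3 > 0).all()

    def test_sampled_taus_recover_implied_taus(self):
        """Sampling then tau recovers (2/pi) arcsin(rho) for every pair."""
        u = sample_t_copula(DEFAULT_RHO, DEFAULT_NU, 25_188, np.random.default_rng(8))
        for i in range(5):
            for j in range(i + 1, 5):
                tau = kendall_tau(u[:, i], u[:, j])
                assert tau == pytest.approx(copula_implied_tau(DEFAULT_RHO[i, j]), abs=0.015)

    def test_fit_sample_fit_round_trip(self, fitted):
        """Refitting to a sampled population reproduces rho within 0.03."""
        sim = fitted.sample(25_188, 17)
        refit = fit_copula(sim)
        assert np.max(np.abs(refit.rho - fitted.rho)) < 0.03


class TestAgeStratified:
    def test_window_filter(self, cohort_frame):
        res = fit_age_stratified(cohort_frame, 53.0, window=0.5, min_records=50)
        used = res.model.data
        assert used.age.between(52.5, 53.5).all()

    def test_empty_stratum_errors(self, cohort_frame):
        with pytest.raises(ValueError, match="records"):
            fit_age_stratified(cohort_frame, 40.0, window=0.0)

    def test_target_age_range(self, cohort_frame):
        with pytest.raises(ValueError):
            fit_age_stratified(cohort_frame, 35.0)

    def test_one_model_per_integer_age(self):
        frame = generate_cohort_frame(FixtureSpec(n=25_188, seed=30))
        models = {
            age: fit_age_stratified(frame, float(age), min_records=30)
            for age in range(40, 75)
        }
        assert len(models) == 35


class TestGoodnessOfFit:
    def test_self_consistency(self, fitted, cohort_frame):
        report = goodness_of_fit(fitted, cohort_frame, n_replicates=40, seed=5)
        assert len(report.tau_table) == 10  # C(5,2)
        assert report.n_pairs_inside_ci() >= 8
        t = report.tau_table
        assert ((t.ci_low <= t.tau_sim_mean) & (t.tau_sim_mean <= t.ci_high)).all()
        m = report.marginal_table
        np.testing.assert_allclose(m.sim_mean, m.real_mean, rtol=0.1)

    def test_misfit_detected(self, cohort_frame):
        """An independence copula cannot explain a rho=0.64 pair."""
        indep = fit_copula(generate_cohort_frame(FixtureSpec(n=4000, seed=77, rho=np.eye(5))))
        report = goodness_of_fit(indep, cohort_frame, n_replicates=25, seed=6)
        row = report.tau_table.set_index("pair").loc["breast_volume_cm3;dense_volume_cm3"]
        assert not (row.ci_low <= row.tau_real <= row.ci_high)

    def test_replicate_floor(self, fitted, cohort_frame):
        with pytest.raises(ValueError):
            goodness_of_fit(fitted, cohort_frame, n_replicates=1)

    def test_report_formats(self, fitted, cohort_frame):
        report = fitted.goodness_of_fit(n_replicates=3, seed=1)
        assert "tau_real" in str(report)


def test_sample_population_wrapper(fitted):
    frame = sample_population(fitted, 100, seed=9)
    assert list(frame.columns) == list(COLUMNS)
    assert len(frame) == 100
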