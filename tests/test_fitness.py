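"""Spline fitness surfaces: peak recovery, pre/post trends, mediation."""

import numpy as np
import pandas as pd
import pytest

from thermotrack.fitness import (_Scaler, compare_with_mismatch_covariate,
                                 fit_fitness_spline_model,
                                 fit_prepost_peak_trends,
                                 locate_peak_with_interval)
from thermotrack.intervals import Period, relative_period_temperature_table
from thermotrack.io import BreedingAttempt
from thermotrack.phenology import compute_match_table, half_fall_date
from thermotrack.simulate import (GeneratorTruth, simulate_breeding_cohort,
                                  simulate_caterpillar_falls, simulate_climate)


@pytest.fixture(scope="module")
def clutch_fit(cohort):
    _, attempts, _, temps = cohort
    return fit_fitness_spline_model(attempts, temps, "clutch_size", "laying")


def _log_quadratic_cohort(rng, n=2000, topt=11.8, width=2.2, temp_sd=1.5,
                          base=2.2):
    """Poisson counts with a log-quadratic temperature hump + crossed REs."""
    years = rng.integers(0, 25, n)
    fems = rng.integers(0, 120, n)
    temp = rng.normal(topt, temp_sd, n)
    eta = base - (temp - topt) ** 2 / (2 * width ** 2) \
        + rng.normal(0, 0.1, 25)[years] + rng.normal(0, 0.1, 120)[fems]
    y = np.maximum(rng.poisson(np.exp(eta)), 1)
    attempts = [BreedingAttempt(f"q{i}", 2000 + int(years[i]), f"f{fems[i]}",
                                20 + int(rng.integers(0, 10)), int(y[i]),
                                min(int(y[i]), 2), 0, int(rng.integers(0, 8)))
                for i in range(n)]
    temps = pd.DataFrame({
        "attempt_id": [a.attempt_id for a in attempts],
        "period": "laying", "mean_temp": temp,
        "start_april_day": 20, "end_april_day": 27,
        "year": [a.year for a in attempts],
        "female_id": [a.female_id for a in attempts],
        "n_days": 8, "n_missing": 0})
    return attempts, temps


class TestSplineModel:
    def test_log_quadratic_optimum_recovered(self, rng):
        """Argmax within 0.5 degC of a planted 11.8 degC log-quadratic optimum."""
        attempts, temps = _log_quadratic_cohort(rng)
        fit = fit_fitness_spline_model(attempts, temps, "clutch_size", "laying")
        peak = locate_peak_with_interval(fit, n_boot=0)
        assert abs(peak.peak_temp - 11.8) <= 0.5
        assert not peak.at_boundary

    def test_cohort_peak_near_generator_optimum(self, clutch_fit, default_truth):
        """Full-generator recovery: argmax within 1 degC of the planted optimum
        (laying-window temperatures are noisy proxies of the generative
        exposure, so single-cohort argmaxes scatter more than in the direct
        construction above; the bootstrap interval test below is the
        calibrated check)."""
        peak = locate_peak_with_interval(clutch_fit, n_boot=0)
        assert abs(peak.peak_temp - default_truth.fitness_optimum_Topt) <= 1.0
        assert not peak.at_boundary

    def test_grid_resolution_is_tenth_degree(self, clutch_fit):
        steps = np.diff(clutch_fit.grid)
        assert np.allclose(steps, 0.1, atol=1e-9)

    def test_clutch_size_restricted_to_laying(self, cohort):
        _, attempts, _, temps = cohort
        with pytest.raises(ValueError, match="laying"):
            fit_fitness_spline_model(attempts, temps, "clutch_size", "incubation")

    def test_family_assignment(self, cohort):
        _, attempts, _, temps = cohort
        f = fit_fitness_spline_model(attempts, temps, "n_fledged", "laying")
        assert f.family == "zip"
        assert 0.0 <= f.model.zip_pi < 0.3
        g = fit_fitness_spline_model(attempts, temps, "fledging_success", "laying")
        assert g.family == "binomial"
        assert np.all((g.curve >= 0) & (g.curve <= 1))

    def test_zip_pi_matches_generator(self, cohort, default_truth):
        _, attempts, _, temps = cohort
        f = fit_fitness_spline_model(attempts, temps, "n_fledged", "laying")
        assert f.model.zip_pi == pytest.approx(default_truth.zero_inflation_pi,
                                               abs=0.05)

    def test_all_successes_predict_near_one(self, cohort):
        _, attempts, _, temps = cohort
        full = [BreedingAttempt(a.attempt_id, a.year, a.female_id, a.laying_date,
                                a.clutch_size, a.clutch_size, a.n_recruits
                                if a.n_recruits <= a.clutch_size else a.clutch_size,
                                a.n_neighbors, a.incubation_start, a.hatch_date)
                for a in attempts]
        f = fit_fitness_spline_model(full, temps, "fledging_success", "laying")
        assert f.curve.min() > 0.95
        assert "possible separation" in f.flags or f.curve.min() > 0.95


class TestPeakInterval:
    def test_monotone_response_flags_boundary(self, rng):
        """A log-linear (never hump-shaped) response peaks at the grid edge."""
        n, n_year = 1500, 25
        years = rng.integers(0, n_year, n)
        fems = rng.integers(0, 90, n)
        temp = rng.normal(11, 1.5, n)
        y = rng.poisson(np.exp(0.8 + 0.3 * (temp - 11)))
        attempts = [BreedingAttempt(f"m{i}", 2000 + int(years[i]), f"f{fems[i]}",
                                    20, max(int(y[i]), 1), min(int(y[i]), 1), 0, 3)
                    for i in range(n)]
        temps = pd.DataFrame({
            "attempt_id": [a.attempt_id for a in attempts],
            "period": "laying", "mean_temp": temp,
            "start_april_day": 20, "end_april_day": 27,
            "year": [a.year for a in attempts],
            "female_id": [a.female_id for a in attempts],
            "n_days": 8, "n_missing": 0})
        fit = fit_fitness_spline_model(attempts, temps, "clutch_size", "laying")
        peak = locate_peak_with_interval(fit, n_boot=0)
        assert peak.at_boundary
        trend = fit_prepost_peak_trends(fit, peak)
        assert any("boundary" in f for f in trend.flags)

    def test_bootstrap_interval_brackets_point(self, clutch_fit):
        peak = locate_peak_with_interval(clutch_fit, n_boot=60, seed=7)
        lo, hi = peak.interval
        assert lo <= peak.peak_temp <= hi
        assert len(peak.boot_peaks) == 60

    def test_bootstrap_is_seed_deterministic(self, clutch_fit):
        p1 = locate_peak_with_interval(clutch_fit, n_boot=25, seed=3)
        p2 = locate_peak_with_interval(clutch_fit, n_boot=25, seed=3)
        assert p1.interval == p2.interval


class TestPrePostTrends:
    def test_symmetric_hump_gives_opposed_slopes(self, rng):
        """Symmetric hump + symmetric design: pre ~ -post within joint CI."""
        attempts, temps = _log_quadratic_cohort(rng)
        fit = fit_fitness_spline_model(attempts, temps, "clutch_size", "laying")
        peak = locate_peak_with_interval(fit, n_boot=0)
        t = fit_prepost_peak_trends(fit, peak)
        assert t.prepeak_slope > 0 > t.postpeak_slope
        joint_hw = (t.prepeak_ci[1] - t.prepeak_ci[0]) / 2 \
            + (t.postpeak_ci[1] - t.postpeak_ci[0]) / 2
        assert abs(t.prepeak_slope + t.postpeak_slope) < max(joint_hw, 0.05)

    def test_cohort_slope_signs_match_curvature(self, clutch_fit):
        """On the study-scale cohort the hump always yields +pre / -post."""
        peak = locate_peak_with_interval(clutch_fit, n_boot=0)
        t = fit_prepost_peak_trends(clutch_fit, peak)
        assert t.prepeak_slope > 0 > t.postpeak_slope

    def test_within_subset_standardization(self, clutch_fit):
        peak = locate_peak_with_interval(clutch_fit, n_boot=0)
        temps = clutch_fit.data["temp"].to_numpy()
        for mask in (temps <= peak.peak_temp, temps > peak.peak_temp):
            z = _Scaler(temps[mask])(temps[mask])
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_observations_at_peak_counted_once(self, clutch_fit):
        peak = locate_peak_with_interval(clutch_fit, n_boot=0)
        t = fit_prepost_peak_trends(clutch_fit, peak)
        assert t.n_pre + t.n_post == clutch_fit.n_obs


@pytest.fixture(scope="module")
def mediation_cohort():
    """Fitness driven purely by trophic mismatch (no laying plasticity)."""
    truth = GeneratorTruth(seed=606, fledge_driver="mismatch",
                           plasticity_gamma=0.0, laying_sd=6.0,
                           daily_sd=1.2, zero_inflation_pi=0.0,
                           n_females=34)
    clim = simulate_climate(truth)
    attempts = simulate_breeding_cohort(clim, truth)
    falls = simulate_caterpillar_falls(clim, truth)
    hfs = [half_fall_date(s) for s in falls if s.usable]
    match = compute_match_table(attempts, hfs)
    temps = relative_period_temperature_table(attempts, clim)
    return attempts, temps, match


class TestMediation:
    def test_full_mediation_attenuates_postpeak_slope(self, mediation_cohort):
        attempts, temps, match = mediation_cohort
        med = compare_with_mismatch_covariate(attempts, temps, match,
                                              "fledging_success")
        assert med.attenuation < 0.3

    def test_structure_two_curves_one_factor(self, mediation_cohort):
        attempts, temps, match = mediation_cohort
        med = compare_with_mismatch_covariate(attempts, temps, match, "n_fledged")
        assert med.curve_without.shape == med.curve_with.shape == med.grid.shape
        assert np.isfinite(med.attenuation)

    def test_independent_mismatch_leaves_curve_unchanged(self, cohort):
        """Temperature-driven cohort: controlling mismatch barely moves things."""
        _, attempts, falls, temps = cohort
        hfs = [half_fall_date(s) for s in falls if s.usable]
        match = compute_match_table(attempts, hfs)
        med = compare_with_mismatch_covariate(attempts, temps, match,
                                              "fledging_success")
        # predicted curves agree to a few percent of the probability scale
        assert np.nanmax(np.abs(med.curve_with - med.curve_without)) < 0.15
        if np.isfinite(med.attenuation):
            assert 0.5 < med.attenuation < 2.0

    def test_only_fledging_metrics_allowed(self, cohort):
        _, attempts, falls, temps = cohort
        hfs = [half_fall_date(s) for s in falls if s.usable]
        match = compute_match_table(attempts, hfs)
        with pytest.raises(ValueError):
            compare_with_mismatch_covariate(attempts, temps, match, "clutch_size")
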