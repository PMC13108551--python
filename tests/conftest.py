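"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from thermotrack.intervals import relative_period_temperature_table
from thermotrack.simulate import (GeneratorTruth, simulate_breeding_cohort,
                                  simulate_caterpillar_falls, simulate_climate)


@pytest.fixture(scope="session")
def default_truth() -> GeneratorTruth:
    """Study-scale truth: 59 years, ~2000 attempts, optimum planted at 11.8 degC."""
    return GeneratorTruth(seed=424241, fitness_optimum_Topt=11.8, n_females=34)


@pytest.fixture(scope="session")
def cohort(default_truth):
    """(climate, attempts, caterpillar falls, interval-temperature table)."""
    climate = simulate_climate(default_truth)
    attempts = simulate_breeding_cohort(climate, default_truth)
    falls = simulate_caterpillar_falls(climate, default_truth)
    temps = relative_period_temperature_table(attempts, climate)
    return climate, attempts, falls, temps


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for structural tests: 20 years x 15 females."""
    truth = GeneratorTruth(seed=77, n_females=15, year_start=2000, year_end=2019,
                           caterpillar_missing_years=())
    climate = simulate_climate(truth)
    attempts = simulate_breeding_cohort(climate, truth)
    falls = simulate_caterpillar_falls(climate, truth)
    temps = relative_period_temperature_table(attempts, climate)
    return truth, climate, attempts, falls, temps


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
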