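"""Shared fixtures: rate tables and simulated cohorts reused across test modules."""

import numpy as np
import pytest

from excessrisk import (AnalysisSpec, RateShapeSpec, SimConfig, make_reference_rates,
                        simulate_cohort)


def flat_rate_spec(cancer_rates: dict, mortality: float) -> RateShapeSpec:
    """A spec whose generated table has the same constant rates in every cell."""
    return RateShapeSpec(cancer_types=dict(cancer_rates), age_slope=0.0,
                         calendar_drift=0.0, deprivation_gradient=0.0,
                         mortality_rate_at_reference=mortality,
                         mortality_age_slope=0.0)


@pytest.fixture(scope="session")
def table():
    """Default age-increasing synthetic reference-rate table."""
    return make_reference_rates(RateShapeSpec(), seed=1)


@pytest.fixture(scope="session")
def null_cohort(table):
    """20k women simulated with every multiplier at 1.0 against ``table``."""
    return simulate_cohort(SimConfig(n=20_000, seed=3), table)


@pytest.fixture(scope="session")
def small_cohort(table):
    """500 women for brute-force oracle comparisons."""
    return simulate_cohort(SimConfig(n=500, seed=17), table)


@pytest.fixture
def lung_spec():
    return AnalysisSpec(target="lung")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
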