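import pytest

from crcisim import (
    default_registry,
    load_demographic_spec,
    run_scenario,
    sample_households,
)
from crcisim.scenario import ScenarioConfig, assign_risk_factors

SEED = 1
N_LARGE = 20_000

#: Published age/sex band shares (percent of individuals, percent of
#: households with a member in the band) used as soft calibration targets.
MARGINAL_TARGETS = {
    "Baby 0 to 11 months": (1.2, 2.8),
    "Infant 12 to 23 months": (1.3, 3.0),
    "Infant 2 years": (1.3, 3.0),
    "Infant 3 years": (1.3, 3.0),
    "Child 4 to 15 years": (13.5, 23.3),
    "Youth 16 to 19 years": (4.7, 8.6),
    "Female 20 to 25 years": (3.8, 7.9),
    "Female 26 to 49 years": (17.2, 39.9),
    "Female 50 to 59 years": (6.1, 13.6),
    "Female 60 to 64 years": (2.9, 6.7),
    "Female 65 to 70 years": (2.8, 6.6),
    "Female 71 to 74 years": (1.7, 3.9),
    "Female 75 years plus": (4.6, 10.5),
    "Male 20 to 25 years": (3.6, 7.1),
    "Male 26 to 59 years": (22.6, 49.9),
    "Male 60 to 64 years": (2.8, 6.2),
    "Male 65 to 70 years": (2.9, 6.7),
    "Male 71 to 74 years": (1.4, 3.2),
    "Male 75 years plus": (3.1, 7.2),
}


@pytest.fixture(scope="session")
def spec():
    return load_demographic_spec()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def population_20k(spec):
    return sample_households(spec, N_LARGE, seed=SEED)


@pytest.fixture(scope="session")
def population_20k_flagged(spec, population_20k):
    return assign_risk_factors(population_20k, spec, mode="none", seed=SEED)


@pytest.fixture(scope="session")
def baseline_run(spec, registry):
    """Full 20k-household scenario run, 10% effect, no clustering."""
    return run_scenario(
        ScenarioConfig(intervention_effect=0.1, n_households=N_LARGE, seed=SEED),
        spec,
        registry,
    )
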