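import numpy as np
import pytest
from hypothesis import settings

import ensemblemap as em

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Ten-dataset cohort, one planted binder, no map noise."""
    return em.simulate_soak_cohort(
        10, 0.1, (0.28, 0.32), em.SimulationConfig(seed=5, noise_sd=0.0)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Thirty-dataset cohort, three planted binders, 0.1-sigma map noise."""
    return em.simulate_soak_cohort(
        30, 0.1, (0.15, 0.3), em.SimulationConfig(seed=9, noise_sd=0.1)
    )


@pytest.fixture(scope="session")
def temperature_series():
    """Four-temperature two-state series at the 100-278 K ladder, 0.05-sigma noise."""
    return em.simulate_temperature_series(
        em.DEFAULT_TEMPERATURE_LADDER, em.SimulationConfig(seed=7, noise_sd=0.05)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map():
    """4x4x4 ramp map with non-trivial origin/spacing."""
    vals = np.arange(64, dtype=float).reshape(4, 4, 4)
    return em.DensityMap(vals, origin=np.array([1.0, -2.0, 0.5]), spacing=np.full(3, 0.5))
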