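import numpy as np
import pytest

from mirisk import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort() -> sd.SyntheticCohort:
    """Moderate-signal cohort shared by fast tests (300 samples, 200 miRNAs)."""
    config = sd.SimulationConfig(
        n_cases=200,
        n_controls=100,
        n_mirnas=200,
        n_informative=10,
        effect_size=1.0,
        seed=11,
    )
    return sd.generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort() -> sd.SyntheticCohort:
    """Pure-noise cohort: no planted miRNAs, no covariate/label association."""
    config = sd.SimulationConfig(
        n_cases=150,
        n_controls=150,
        n_mirnas=200,
        n_informative=0,
        effect_size=0.0,
        covariate_effect=0.0,
        seed=7,
    )
    return sd.generate_cohort(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
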