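import warnings

import pytest

from rgepdeconv.synthetic import CohortConfig, simulate_cohort


def small_config(**overrides) -> CohortConfig:
    """A fast three-source cohort for structural tests."""
    defaults = dict(
        n_patients_per_source={"blood": 2, "tumorA": 3, "tumorB": 2},
        cells_per_sample=60,
        seed=3,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(small_config(noise_sd=0.0, dropout_rate=0.0,
                                        patient_shift_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Dropped-column / dropped-marker warnings are part of normal operation."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*column\\(s\\) dropped.*")
        warnings.filterwarnings("ignore", message=".*marker genes absent.*")
        warnings.filterwarnings("ignore", message=".*gene-set genes present.*")
        yield
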