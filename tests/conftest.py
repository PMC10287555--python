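import pytest

from ddrtx.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient cohort under default (trial-like) conditions."""
    config = CohortConfig(n_patients=40, seed=11)
    patients, truth = simulate_cohort(config)
    return patients, truth


@pytest.fixture()
def make_cohort():
    def _make(**kwargs):
        return simulate_cohort(CohortConfig(**kwargs))
    return _make
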