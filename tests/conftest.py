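import numpy as np
import pytest

from neuroprog.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale cohort: 60 subjects, 16^3 grids."""
    return GeneratorConfig(n_subjects=60, grid_shape=(16, 16, 16), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, volumes = generate_cohort(small_config, with_volumes=True)
    return records, volumes


@pytest.fixture(scope="session")
def full_cohort_records():
    """Default cohort (n=332), records only — shared across tests."""
    records, _ = generate_cohort(GeneratorConfig(seed=7), with_volumes=False)
    return records
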