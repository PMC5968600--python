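import numpy as np
import pytest
from hypothesis import settings

from twinherit.synthetic_cohort import SimulationConfig, simulate_cohort
from twinherit import refraction

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the study's scale (135 MZ + 95 DZ pairs)."""
    return simulate_cohort(SimulationConfig(seed=20240915))


@pytest.fixture(scope="session")
def classified(study_cohort):
    return refraction.classify_cohort(study_cohort.cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
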