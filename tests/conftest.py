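import logging

import numpy as np
import pytest

from gaoof import (
    GAConfig,
    SyntheticConfig,
    default_rules,
    generate_cohort,
)
from gaoof.synthetic import null_config

logging.getLogger("gaoof").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def small_ga():
    """A deliberately small GA for fast pipeline tests."""
    return GAConfig(population_size=16, n_generations=8, inner_k=3, seed=42)


@pytest.fixture(scope="session")
def informative_cohort():
    """n=2000 cohort with the default (moderately informative) weights."""
    return generate_cohort(SyntheticConfig(n_participants=2000, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """n=2000 cohort whose outcome is independent of every feature."""
    return generate_cohort(null_config(2000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
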