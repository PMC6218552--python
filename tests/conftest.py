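import numpy as np
import pytest

from semlseffect import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration cohort at the canonical size (2,333 limbs)."""
    return generate_cohort(default_config(), seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """Bigger default cohort for Monte-Carlo checks."""
    return generate_cohort(default_config(n_limbs=20_000), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
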