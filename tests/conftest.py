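import numpy as np
import pytest

from abrsig.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2-subject cohort with waveforms, for IO and extraction tests."""
    cfg = CohortConfig(n_asd=1, n_nonasd=1, trials_per_db=1, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 20+20 subjects, 3 dB x 2 ears x 2 trials."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
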