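import numpy as np
import pytest

import blastdm as b


@pytest.fixture(scope="session")
def novice_hyper():
    return b.default_novice_hyper()


@pytest.fixture(scope="session")
def small_cohort_trials(novice_hyper):
    """Three novices' full simulated experiments (DDM ground truth)."""
    profiles = b.sample_participants(novice_hyper, 3, seed=11)
    cfg = b.ExperimentConfig(rng_seed=11)
    return b.simulate_dataset(profiles, cfg, model="ddm", seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
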