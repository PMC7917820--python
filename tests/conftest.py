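import numpy as np
import pytest
from hypothesis import settings

import spikesom as sp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return sp.build_channel_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort: 10 players x 6 spikes, seed 0."""
    trials, manifest = sp.generate_cohort(sp.SyntheticConfig(seed=0))
    return trials, manifest


@pytest.fixture(scope="session")
def cohort_means(default_cohort):
    trials, _ = default_cohort
    pre = [sp.preprocess_trial(t) for t in trials]
    return sp.condition_means(pre)


@pytest.fixture(scope="session")
def fast_som_config():
    """Quarter-size map and short schedules: keeps SOM tests quick while
    exercising the same code path as the full configuration."""
    return sp.SOMConfig(map_scale="small", phase1_epochs=3, phase2_epochs=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
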