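import numpy as np
import pytest

from wholereport.synth import (
    ObserverConfig,
    sample_stimuli,
    simulate_grouping_observer,
    simulate_independent_observer,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def continuous_dataset():
    """Small independent-observer dataset on the continuous task (30 trials, N=4)."""
    stim = sample_stimuli("continuous", 4, 30, np.random.default_rng(7))
    cfg = ObserverConfig(kind="independent", kappa_report=10.0, guess_rate=0.1, seed=8)
    return simulate_independent_observer(stim, cfg, "continuous", "p01")


@pytest.fixture(scope="session")
def discrete_dataset():
    """Small grouping-observer dataset on the discrete task (30 trials, N=6)."""
    stim = sample_stimuli("discrete", 6, 30, np.random.default_rng(9))
    cfg = ObserverConfig(kind="grouping", ordering="similarity_chain",
                         kappa_report=8.0, seed=10)
    return simulate_grouping_observer(stim, cfg, "discrete", "p02")
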