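import numpy as np
import pytest

from prhpop import events, trial_world
from prhpop.trial_world import PlantedEffects, StageConfig


@pytest.fixture(scope="session")
def small_bundle():
    """A T2 session small enough for fast decoding tests."""
    cfg = StageConfig.for_stage("T2")
    fx = PlantedEffects(n_neurons=24)
    return trial_world.simulate_session(cfg, 60, fx, seed=123)


@pytest.fixture(scope="session")
def small_events(small_bundle):
    em = events.estimate_events(small_bundle.fluorescence,
                                small_bundle.frame_rate_hz)
    return em.s_hat


@pytest.fixture
def rng():
    return np.random.default_rng(0)
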