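import numpy as np
import pytest

from sacattn.config import (DetectionParams, EyeModel, NeuronModel, TaskConfig)
from sacattn.eye import detect_session
from sacattn.spikes import normalize_session
from sacattn.synthetic import simulate_session


def small_task(**kw) -> TaskConfig:
    """A shortened session: 2 blocks of 40 trials, 10 transition trials."""
    defaults = dict(trials_per_block=40, single_patch_trials_per_transition=10,
                    change_window_ms=(1000.0, 2000.0))
    defaults.update(kw)
    return TaskConfig(**defaults)


@pytest.fixture(scope="session")
def session_small():
    """One small simulated session shared by read-only tests."""
    return simulate_session(small_task(), EyeModel(),
                            [NeuronModel() for _ in range(4)], seed=20240901)


@pytest.fixture(scope="session")
def events_small(session_small):
    return detect_session(session_small, DetectionParams())


@pytest.fixture(scope="session")
def norm_small(session_small):
    return normalize_session(session_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
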