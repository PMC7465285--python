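import numpy as np
import pytest

from miwl.simulate import SimulationConfig, make_session


@pytest.fixture(scope="session")
def default_session():
    """A short two-segment session with blinks and artifacts enabled."""
    cfg = SimulationConfig(seed=11, lap_plan=[("Easy", 60.0), ("Hard", 60.0)])
    rec, trace = make_session(cfg)
    return cfg, rec, trace


@pytest.fixture(scope="session")
def clean_session():
    """Same plan with blink/artifact rates zero (clean EEG)."""
    cfg = SimulationConfig(
        seed=11, lap_plan=[("Easy", 60.0), ("Hard", 60.0)],
        blink_rate_hz=0.0, artifact_rate_hz=0.0,
    )
    rec, trace = make_session(cfg)
    return cfg, rec, trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
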