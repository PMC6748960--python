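import numpy as np
import pytest

from cbgreach.config import RunConfig
from cbgreach.model import build_hemisphere, build_model
from cbgreach.protocols import pretrain_model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cfg():
    return RunConfig().validate()


def small_config() -> RunConfig:
    """Scaled-down build (fewer babbles / SOM steps) for structural tests."""
    c = RunConfig()
    c.train.n_babble = 150
    c.train.loop_sweeps = 4
    c.som.n_steps = 1500
    return c.validate()


@pytest.fixture(scope="session")
def small_hemisphere():
    return build_hemisphere(small_config(), np.random.default_rng(11))


@pytest.fixture(scope="session")
def trained_model():
    """One fully pretrained bimanual model (default study conditions)."""
    return pretrain_model(RunConfig().validate(), seed=3)
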