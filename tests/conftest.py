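import numpy as np
import pytest

import planargait as pg


@pytest.fixture(scope="session")
def model():
    """Default skeleton, 22 muscles, and path model."""
    return pg.build_model()


@pytest.fixture(scope="session")
def dynamics(model):
    skel, muscles, paths = model
    return pg.WalkerDynamics(skel, paths, muscles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_env(mode="compat-22", seed=0, max_steps=100, **kw):
    return pg.PlanarWalkEnv(pg.EpisodeConfig(
        seed=seed, mode=mode, max_steps=max_steps, **kw))


@pytest.fixture()
def env_factory():
    return make_env
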