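import numpy as np
import pytest

from vesselseg.phantom import PhantomConfig, make_phantom_store


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_phantom_store(tmp_path_factory):
    """A 96^3 bright-vessel phantom store shared across tests."""
    path = tmp_path_factory.mktemp("stores") / "phantom96"
    cfg = PhantomConfig(shape=(96, 96, 96), seed=11)
    return make_phantom_store(cfg, path)


@pytest.fixture(scope="session")
def tiny_phantom_store(tmp_path_factory):
    """A 48^3 phantom store for fast smoke tests."""
    path = tmp_path_factory.mktemp("stores") / "phantom48"
    cfg = PhantomConfig(shape=(48, 48, 48), seed=7, radius_range=(2.0, 4.0))
    return make_phantom_store(cfg, path, chunk_shape=(32, 32, 32))
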