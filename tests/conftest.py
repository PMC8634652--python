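import numpy as np
import pytest

import synseek as ss

SMALL_PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def small_config() -> ss.PhantomConfig:
    """A compact phantom: 10 sections, ~65 px planes, a handful of events."""
    return ss.PhantomConfig(
        volume_size_um=(20.0, 20.0, 0.9),
        n_dendrites=3,
        n_axons=6,
        n_synapses=3,
        n_near_misses=3,
        tile_grid=(2, 2),
        seed=SMALL_PHANTOM_SEED,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return ss.generate_phantom(small_config)


@pytest.fixture(scope="session")
def small_params() -> ss.DetectionParams:
    # FOV shrunk to fit the small planes (default 33 um would exceed them).
    return ss.DetectionParams(fov_um=8.0)


@pytest.fixture(scope="session")
def small_detection(small_phantom, small_params):
    stack, _ = small_phantom
    return ss.run_detect(stack, params=small_params)


@pytest.fixture(scope="session")
def default_phantom():
    """The full default phantom used for end-to-end checks (seed 42)."""
    return ss.generate_phantom(ss.PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def default_detection(default_phantom):
    stack, _ = default_phantom
    return ss.run_detect(stack)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
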