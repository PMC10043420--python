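import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rhizoseg as rz

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_synth_config():
    """64x64 generator profile used throughout the tests."""
    return rz.SyntheticConfig(
        canvas=(64, 64),
        n_primary_roots=1,
        root_width_range=(2.5, 4.5),
        target_foreground_fraction=(0.02, 0.25),
    )


@pytest.fixture(scope="session")
def tiny_samples(tiny_synth_config):
    return rz.generate_samples(6, tiny_synth_config, seed=77)


def small_unet_config(**overrides):
    """A narrow plain U-Net that trains in seconds (unit-test scale)."""
    defaults = dict(variant="unet", base_width=8)
    defaults.update(overrides)
    return rz.ModelConfig(**defaults)


@pytest.fixture
def small_unet():
    return small_unet_config
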