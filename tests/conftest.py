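import numpy as np
import pytest

from fluoroquant import GeneratorConfig, GroupTrend


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast two-group experiment for pipeline tests."""
    return GeneratorConfig(
        image_shape=(96, 96),
        n_plants_per_group=3,
        days=(1, 8, 15),
        n_leaflets=3,
        noise_sd=20.0,
        seed=7,
        groups=(
            GroupTrend("control", 0.810, 0.794, between_plant_sd=0.01,
                       within_plant_spatial_sd=0.02),
            GroupTrend("combination", 0.759, 0.739, between_plant_sd=0.01,
                       within_plant_spatial_sd=0.02),
        ),
    )
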