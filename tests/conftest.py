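import numpy as np
import pytest

from thermofoot.pipeline import preprocess_subject
from thermofoot.synthetic import PhantomConfig, PlantedTableConfig, generate_planted_table, generate_phantom_subject


@pytest.fixture(scope="session")
def clean_phantom_config():
    """Noise-free, hotspot-free phantom: construction is exactly recoverable."""
    return PhantomConfig(noise_sd=0.0, hotspot_count=0, seed=7)


@pytest.fixture(scope="session")
def healthy_subject(clean_phantom_config):
    return generate_phantom_subject(clean_phantom_config, label=0, rng=7, subject_id="h000")


@pytest.fixture(scope="session")
def healthy_processed(healthy_subject):
    """(TemperatureMap, AngiosomeSet, QCResult) of a noise-free healthy subject."""
    s = healthy_subject
    return preprocess_subject(s.gray_image, s.foot_mask, *s.t_range)


@pytest.fixture(scope="session")
def planted_8834():
    """Planted table at the 88:34 case:control imbalance, 10 of 141 informative."""
    cfg = PlantedTableConfig(n_majority=88, n_minority=34, n_features=141,
                             n_informative=10, effect_size=3.0, seed=11)
    return generate_planted_table(cfg)


def quantization_step(config: PhantomConfig) -> float:
    return (config.t_max - config.t_min) / 255.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
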