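import numpy as np
import pandas as pd
import pytest

from polyshift.config import SimConfig
from polyshift.simulate import generate_expression_dataset


def noise_free_config(seed: int = 1, **kw) -> SimConfig:
    base = dict(
        sigma_bio=0.0,
        sigma_tech=0.0,
        sample_scale_range=(1.0, 1.0),
        sample_offset_range=(0.0, 0.0),
        seed=seed,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_expression_dataset(noise_free_config())


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_expression_dataset(SimConfig(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
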