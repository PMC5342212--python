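import numpy as np
import pytest

from morphoscape.landmark_io import LandmarkConfiguration
from morphoscape.synthetic_data import wing_template


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


def random_configs(rng, n, k, noise=0.05, prefix="s"):
    """Template + isotropic noise, randomly rotated/translated/scaled."""
    template = wing_template(k) if k >= 4 else np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]]
    )[:k]
    configs = []
    for i in range(n):
        shape = template + noise * rng.standard_normal((k, 2))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        scale = rng.uniform(50, 150)
        coords = scale * shape @ rot.T + rng.uniform(-100, 100, 2)
        configs.append(LandmarkConfiguration(f"{prefix}{i}", "right", coords))
    return configs


@pytest.fixture
def small_config_factory(rng):
    def factory(n=5, k=18, noise=0.05):
        return random_configs(rng, n, k, noise)

    return factory
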