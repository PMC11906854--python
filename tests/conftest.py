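import numpy as np
import pytest

from cropsuit import pipeline, presets, synthetic
from cropsuit.grids import Grid


@pytest.fixture(scope="session")
def rice_matrix():
    return presets.rice_matrix()


@pytest.fixture(scope="session")
def coconut_matrix():
    return presets.coconut_matrix()


@pytest.fixture(scope="session")
def landscape_config():
    return synthetic.LandscapeConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(landscape_config):
    return synthetic.generate_landscape(landscape_config)


@pytest.fixture(scope="session")
def rice_result(bundle):
    layers = pipeline.prepare_criterion_layers(bundle, "rice")
    result, manifest = pipeline.run_suitability(layers, crop="rice", lulc=bundle["lulc"])
    return result, manifest


def random_reciprocal_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random Saaty-scale positive reciprocal matrix (exact reciprocals)."""
    scale = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = rng.choice(scale)
            if rng.random() < 0.5:
                v = 1.0 / v
            a[i, j] = v
            a[j, i] = 1.0 / v
    return a


def small_grid(values, cell_size=250.0, nodata=-9999.0, units=""):
    return Grid(np.asarray(values, dtype=float), (0.0, 0.0, cell_size), nodata, units)
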