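import numpy as np
import pytest

import wingmorph as wm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wing_template():
    return wm.make_template(11, "wing")


@pytest.fixture
def small_dataset(rng):
    """12 specimens of one synthetic species, k=11, with random frames."""
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 1, 0.0, seed=1)
    return wm.simulate_specimens(means, 12, 0.01, seed=2)


@pytest.fixture
def two_species_refs():
    """Well-separated two-species reference set (separation 20x sigma)."""
    template = wm.make_template(11, "wing")
    means = wm.simulate_species_means(template, 2, 0.2, seed=3)
    return wm.simulate_specimens(means, 15, 0.01, seed=4)


def random_configuration(rng, k=11):
    return wm.LandmarkConfiguration(
        specimen_id=f"r{rng.integers(1e9)}", coords=rng.normal(size=(k, 2))
    )


def random_similarity(coords, rng):
    theta = rng.uniform(0, 2 * np.pi)
    scale = np.exp(rng.uniform(-1, 1))
    shift = rng.uniform(-5, 5, size=2)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return scale * coords @ R.T + shift
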