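import numpy as np
import pytest

import mfquant as m


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale scene: 4 somata, ~20 clusters, default noise."""
    return m.make_scene(
        (600, 600),
        n_somata=4,
        clusters_per_soma_mean=5,
        soma_radius_px=60,
        distractors_per_channel=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_image(small_scene):
    return m.render(small_scene)


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise scene for exact ground-truth checks."""
    return m.make_scene(
        (600, 600),
        n_somata=4,
        clusters_per_soma_mean=5,
        soma_radius_px=60,
        distractors_per_channel=15,
        noise=m.NoiseSpec(gaussian_sd=0.0, baseline=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_image(clean_scene):
    return m.render(clean_scene)


def random_mask(seed: int, shape=(512, 512), density=0.02) -> np.ndarray:
    return np.random.default_rng(seed).random(shape) < density
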