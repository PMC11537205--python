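import numpy as np
import pytest

from phenogate import InstanceMap, default_config, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """A compact noiseless slide shared by read-only tests."""
    cfg = default_config(
        n_cells=140, noise_sd=0.0, seed=11, image_height_px=512, image_width_px=512
    )
    return generate_tissue(cfg)


@pytest.fixture(scope="session")
def noisy_tissue():
    cfg = default_config(
        n_cells=140, noise_sd=0.08, seed=13, image_height_px=512, image_width_px=512
    )
    return generate_tissue(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_map(centers, radii, shape=(64, 64), res=0.5):
    """Instance map with one disk per (center, radius), painted in id order."""
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.indices(shape)
    for i, ((r0, c0), rad) in enumerate(zip(centers, radii), start=1):
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        labels[mask & (labels == 0)] = i
    return InstanceMap(labels, res)
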