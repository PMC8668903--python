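import numpy as np
import pytest

import sbfquant as sq


@pytest.fixture(scope="session")
def desk_spacing():
    return sq.VoxelSpacing(150.0, 150.0, 300.0)


@pytest.fixture(scope="session")
def small_scene():
    """A small but fully featured scene: capillary, nuclei, mitochondria."""
    cfg = sq.SceneConfig(
        dims=(128, 128, 48),
        n_cells=8,
        cell_radius_mean_um=3.0,
        mito_per_cell=(8, 15),
        capillary=sq.CapillarySpec(p0_um=(1.5, 1.5, 7.2), p1_um=(17.5, 17.5, 7.2), radius_um=1.5),
        seed=11,
    )
    return sq.generate_scene(cfg)


def make_textured_slice(shape=(64, 64), sigma=2.0, seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(size=shape), sigma).astype(np.float32) * 50.0
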