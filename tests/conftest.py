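import numpy as np
import pytest

from hcrquant import ImageStack, PhantomParams
from hcrquant.synthetic import PRESETS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast phantom for pipeline-level tests."""
    return small_phantom_params()


def small_phantom_params(**overrides) -> PhantomParams:
    defaults = dict(
        shape_px=(24, 48, 48),
        voxel_size_um=(4.0, 1.6, 1.6),
        epidermis_thickness_um=12.0,
        outer_epidermis_um=5.0,
        n_blood_cells=4,
        blood_cell_radius_um=5.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture
def clean_params():
    """Noise-free, blood-free, background-free small phantom."""
    return small_phantom_params(
        noise_sd=0.0, n_blood_cells=0,
        background_level=(0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture
def dmso():
    return PRESETS["DMSO"]


def random_stack(rng, shape=(2, 4, 6, 5), voxel_size=(2.0, 1.0, 1.0)) -> ImageStack:
    vox = rng.integers(0, 1000, size=shape).astype(np.float32)
    roles = {0: "hcr", 1: "hcr"} if shape[0] == 2 else {
        i: "hcr" for i in range(shape[0])
    }
    names = {i: f"ch{i}" for i in range(shape[0])}
    return ImageStack(vox, voxel_size, channel_roles=roles, channel_names=names)
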