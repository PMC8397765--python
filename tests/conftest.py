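import numpy as np
import pytest

from tendonct import (PhantomSpec, SubVolume, degrade, make_fat_cell_phantom,
                      make_fiber_phantom)


@pytest.fixture
def fiber_spec():
    """Small fiber phantom: fibers of ~5-voxel radius, several per FOV."""
    return PhantomSpec(shape=(64, 96, 96), voxel_size=1.63,
                       fiber_radius=8.0, fiber_gap=3.0)


@pytest.fixture
def fiber_volume(fiber_spec):
    return make_fiber_phantom(fiber_spec)


@pytest.fixture
def fat_spec():
    return PhantomSpec(shape=(64, 64, 64), voxel_size=1.0,
                       sphere_radius_range=(8.0, 14.0), sphere_count=6, seed=4)


@pytest.fixture
def fat_volume(fat_spec):
    return make_fat_cell_phantom(fat_spec)


@pytest.fixture
def noisy_fiber_sub(fiber_volume):
    """Blurred + noisy fiber sub-volume, the typical metric input."""
    d = degrade(fiber_volume, psf_sigma=1.63, noise_sigma=0.05,
                ring_amplitude=0.0, seed=11)
    return SubVolume(d.data, d.voxel_size, "fibers")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
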