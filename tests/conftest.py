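import numpy as np
import pytest

from recurmap.core import GridSpec, ImageVolume, Mask
from recurmap.phantom import PhantomSpec, generate_patient
from recurmap.registration import RigidTransform


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom patient with a fixed rigid offset."""
    spec = PhantomSpec(
        seed=3,
        rigid_offset=RigidTransform.from_euler((2.0, -3.0, 1.0), (6.0, -4.0, 2.0), center=(64.0, 64.0, 48.0)),
    )
    return generate_patient(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return GridSpec((8, 8, 8), (1.0, 1.0, 1.0))


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="CT_HU", origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(values.shape, spacing, origin)
    return ImageVolume(grid=grid, values=values, modality=modality)


def make_mask(membership, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    membership = np.asarray(membership, dtype=bool)
    grid = GridSpec(membership.shape, spacing, origin)
    return Mask(grid=grid, membership=membership)
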