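import numpy as np
import pytest

from octa_deshadow import OctaVolume, PhantomSpec, TailModel, NoiseModel, Vessel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A small random nonnegative volume with anisotropic pitch."""
    data = rng.random((32, 6, 5)) + 0.01
    return OctaVolume(data=data, dz_um=4.0, dx_um=16.0, dy_um=16.0)


@pytest.fixture
def single_tail_spec():
    """A minimal phantom: one vessel with a tail, no capillaries, faint noise."""
    return PhantomSpec(
        shape=(64, 16, 16),
        dz_um=8.0,
        dx_um=16.0,
        dy_um=16.0,
        vessels=[Vessel(center_xy_um=(128.0, 128.0), radius_um=60.0, depth_um=60.0)],
        capillaries=[],
        tail=TailModel(decay_length_um=400.0, strength=0.5),
        noise=NoiseModel(scale=0.005),
        attenuation_length_um=1500.0,
        seed=3,
    )
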