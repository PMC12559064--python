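import numpy as np
import pytest

from perfmosaic.imaging import CTVolume, SegmentationSet
from perfmosaic.phantom import PhantomSpec, generate_chest_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-severity phantom shared by read-only tests."""
    spec = PhantomSpec(seed=7)
    return (spec, *generate_chest_phantom(spec))


@pytest.fixture(scope="session")
def wellsep_spec():
    """Phantom spec with >= 4-SD separated compartments (for MAP checks)."""
    return PhantomSpec(weights=(0.3, 0.4, 0.3), means=(-920.0, -770.0, -620.0),
                       sds=(25.0, 25.0, 25.0), blob_scale=6.0,
                       radial_gradient=0.0, seed=11)


@pytest.fixture(scope="session")
def wellsep_phantom(wellsep_spec):
    return (wellsep_spec, *generate_chest_phantom(wellsep_spec))


def make_block_volume(value=-800.0, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    return CTVolume(data=np.full(shape, float(value), dtype=np.float32),
                    spacing=spacing)


def make_two_box_seg(shape=(12, 12, 12), min_warn_ok=True):
    """Two cuboid 'lungs' and a vein streak between them (tiny, for contracts)."""
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    veins = np.zeros(shape, dtype=bool)
    left[1:5, 2:10, 2:10] = True
    right[7:11, 2:10, 2:10] = True
    veins[5:7, 5:7, 5:7] = True
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny masks trip the size QC warning
        return SegmentationSet(lung_left=left, lung_right=right, veins=veins,
                               grid_shape=shape)
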