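import numpy as np
import pytest

import pvsquant as pq
from pvsquant.image import affine_from_spacing


ANISO_AFFINE = affine_from_spacing((0.8, 0.8, 4.4))


def make_mask(data):
    return pq.BinaryMask(np.asarray(data, dtype=bool), ANISO_AFFINE.copy())


def make_volume(data, modality="T2"):
    return pq.ImageVolume(np.asarray(data, dtype=float), ANISO_AFFINE.copy(), modality)


@pytest.fixture(scope="session")
def counting_case():
    """A 7-tube counting phantom, noise-free (session-cached: read-only)."""
    return pq.generate_phantom(pq.counting_phantom_config(7, grid_dims=(96, 96, 16), seed=11))


@pytest.fixture(scope="session")
def generic_case():
    """A generic isotropic-tube phantom with T2 on its own finer grid."""
    cfg = pq.PhantomConfig(grid_dims=(64, 64, 12), n_tubes=4, seed=5)
    return pq.generate_phantom(cfg)
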