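import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")

from hippodmri.core import DWIDataset, VolumeGrid
from hippodmri.phantom import hardi_scheme, hydi_scheme
from hippodmri.sphere import SphereTessellation


@pytest.fixture(scope="session")
def hydi60():
    """Three-shell ex vivo scheme, 60 directions per shell."""
    return hydi_scheme(n_dirs=60)


@pytest.fixture(scope="session")
def hardi500():
    """Single-shell b = 4500 scheme with 500 directions."""
    return hardi_scheme(n_dirs=500, n_b0=6)


@pytest.fixture(scope="session")
def hardi60():
    return hardi_scheme(n_dirs=60, n_b0=1)


@pytest.fixture(scope="session")
def sphere4():
    """2562-vertex icosphere (1281 antipodal direction pairs)."""
    return SphereTessellation.icosphere(4)


def single_voxel_dataset(signal_1d, scheme):
    grid = VolumeGrid.isotropic((1, 1, 1))
    sig = np.asarray(signal_1d, dtype=float).reshape(1, 1, 1, -1)
    return DWIDataset(grid, sig, scheme, np.ones((1, 1, 1), dtype=bool))
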