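import numpy as np
import pytest

from storemetrics.containers import AcquisitionParams
from storemetrics.synthetic import (
    PhantomCell,
    biconcave_height,
    generate_phantom,
    phantom_presets,
    plateau_edge_modulus,
    synthesize_scan,
    uniform_modulus,
)


def single_cell_phantom(modulus_profile, grid=32, pixel_um=1.0, radius_um=10.0):
    """One centered phantom cell on a small grid."""
    half = grid * pixel_um / 2.0
    cell = PhantomCell(
        center_xy=(half, half),
        radius_um=radius_um,
        height_profile=biconcave_height(),
        modulus_profile=modulus_profile,
    )
    return generate_phantom([cell], (grid, grid), pixel_um)


@pytest.fixture(scope="session")
def noise_free_acq():
    return AcquisitionParams(seed=0)


@pytest.fixture(scope="session")
def center_edge_scan(noise_free_acq):
    """Noise-free 32x32 scan of a 300 Pa-center / 80 Pa-edge cell."""
    phantom = single_cell_phantom(plateau_edge_modulus(300.0, 80.0))
    return phantom, synthesize_scan(phantom, noise_free_acq)


@pytest.fixture(scope="session")
def uniform_300_scan(noise_free_acq):
    """Noise-free 32x32 scan of a uniformly 300 Pa cell."""
    phantom = single_cell_phantom(uniform_modulus(300.0))
    return phantom, synthesize_scan(phantom, noise_free_acq)


@pytest.fixture(scope="session")
def stiff_scan(noise_free_acq):
    """Noise-free 32x32 scan of a near-rigid (1 MPa) cell."""
    phantom = single_cell_phantom(uniform_modulus(1.0e6))
    return phantom, synthesize_scan(phantom, noise_free_acq)
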