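import numpy as np
import pytest

from ctialps import PhantomSpec, ReconConfig, Region
from ctialps.mrept import MU0, OMEGA_3T
from ctialps.phantom import make_default_scheme


@pytest.fixture(scope="session")
def scheme():
    return make_default_scheme()


@pytest.fixture(scope="session")
def two_region_spec():
    """64x64 slice: 40-mm disk at 1.8 S/m in a 0.6 S/m background."""
    return PhantomSpec(
        shape=(64, 64, 1),
        voxel_size_mm=(2.0, 2.0, 5.0),
        regions=[
            Region(kind="background", sigma=0.6),
            Region(kind="sphere", center_mm=(0, 0, 0), size_mm=40.0, sigma=1.8),
        ],
    )


@pytest.fixture
def analytic_cfg():
    """Reconstruction config for analytic phantoms: no phase smoothing."""
    return ReconConfig(smooth_fwhm_vox=0.0)


def quadratic_phase(sigma0, nx, ny, h_m):
    """Analytic homogeneous-medium transceive phase omega*mu0*sigma0*(x^2+y^2)/2."""
    x = (np.arange(nx) - (nx - 1) / 2.0) * h_m
    y = (np.arange(ny) - (ny - 1) / 2.0) * h_m
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return OMEGA_3T * MU0 * sigma0 * (xx**2 + yy**2) / 2.0


@pytest.fixture(scope="session")
def quadratic_phase_field():
    return quadratic_phase
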