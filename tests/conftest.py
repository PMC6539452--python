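import numpy as np
import pytest

from xfct import physics as ph
from xfct.forward import AcquisitionProtocol, simulate_xfct
from xfct.geometry import SystemGeometry, VoxelGrid
from xfct.phantom import GroundTruth, calibration_phantom, rasterize


@pytest.fixture(scope="session")
def geom():
    return SystemGeometry()


@pytest.fixture(scope="session")
def tube_spectrum():
    return ph.IncidentSpectrum.filtered_tube(140.0, 0.4)


@pytest.fixture(scope="session")
def ct_spectrum():
    return ph.IncidentSpectrum.filtered_tube(65.0, 0.1)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 64 mm field for fast forward simulations."""
    return VoxelGrid(64, 64, 1.0)


@pytest.fixture(scope="session")
def small_calibration_truth(small_grid):
    return rasterize(calibration_phantom(), small_grid)


@pytest.fixture(scope="session")
def small_protocol():
    return AcquisitionProtocol(n_views=12, source_fluence=1.0e9)


@pytest.fixture(scope="session")
def small_noiseless_sinograms(small_calibration_truth, geom, tube_spectrum, small_protocol):
    """Noiseless three-bin simulation of the calibration phantom (coarse grid)."""
    return simulate_xfct(
        small_calibration_truth, geom, tube_spectrum, small_protocol, noise=False
    )


@pytest.fixture(scope="session")
def zero_gd_truth(small_grid):
    """Water disc with no Gd anywhere."""
    from xfct.phantom import PhantomSpec

    return rasterize(PhantomSpec("water", 1.0, (20.0, 20.0)), small_grid)
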