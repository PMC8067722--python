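import numpy as np
import pytest

import rtforecast as rt
from rtforecast.grids import CapacityState
from rtforecast.solver import SolverConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """Isotropic-in-plane 8x8x4 grid with a full brain mask."""
    return rt.Grid3D(8, 8, 4)


def uniform_capacity(shape, theta_min=0.1, theta_max=0.9, theta_V=0.3,
                     phi_V_thresh=0.05):
    return CapacityState(theta_T=np.full(shape, theta_max),
                         theta_min=theta_min, theta_max=theta_max,
                         theta_V=theta_V, phi_V_thresh=phi_V_thresh)


@pytest.fixture
def capacity_factory():
    return uniform_capacity


@pytest.fixture(scope="session")
def fast_config():
    """Solver configuration without the elasticity solve (lambda1 effect off)."""
    return SolverConfig(mechanics=False)


@pytest.fixture(scope="session")
def animal3_noiseless():
    """Noiseless virtual animal on a small grid (ground truth known)."""
    grid = rt.default_grid(16, 16, 4)
    truth = rt.default_truth("animal3", seed=7, noise_snr=np.inf)
    ds = rt.generate_virtual_animal(truth, grid, capacity="truth",
                                    config=SolverConfig(mechanics=False))
    return ds, truth


@pytest.fixture(scope="session")
def animal3_noisy():
    """SNR-20 virtual animal on a small grid."""
    grid = rt.default_grid(16, 16, 4)
    truth = rt.default_truth("animal3", seed=7, noise_snr=20.0)
    ds = rt.generate_virtual_animal(truth, grid, capacity="truth",
                                    config=SolverConfig(mechanics=False))
    return ds, truth
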