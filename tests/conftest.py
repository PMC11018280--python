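import numpy as np
import pytest

from frontcontrol.model_core import (
    DensityProfile,
    GenericParams,
    SpatialGrid,
    SpongyParams,
    gaussian_kernel,
)
from frontcontrol.optimizer import natural_front
from frontcontrol.treatment_solver import SpeedTarget


@pytest.fixture(scope="session")
def generic_params() -> GenericParams:
    return GenericParams(r=2.0, k=2.0, gamma=1.0, sigma=25.0, beta=1.25,
                         alpha=0.2)


@pytest.fixture(scope="session")
def spongy_params() -> SpongyParams:
    return SpongyParams.normalized(r=2.0, k_lambda0=100.0, a=0.08,
                                   sigma=10.0)


@pytest.fixture(scope="session")
def generic_grid() -> SpatialGrid:
    # moderate resolution keeps the unit suite fast; acceptance tests use
    # the documented default resolution
    return SpatialGrid.for_sigma(25.0, length_in_sigma=30.0,
                                 cells_per_sigma=10.0)


@pytest.fixture(scope="session")
def spongy_grid() -> SpatialGrid:
    return SpatialGrid(-120.0, 120.0, 0.5)


@pytest.fixture(scope="session")
def generic_kernel(generic_grid, generic_params):
    return gaussian_kernel(generic_grid, generic_params.sigma)


@pytest.fixture(scope="session")
def generic_natural_front(generic_params, generic_grid) -> DensityProfile:
    return natural_front(generic_params, generic_grid)


@pytest.fixture(scope="session")
def spongy_natural_front(spongy_params, spongy_grid) -> DensityProfile:
    return natural_front(spongy_params, spongy_grid, shape_tol=1e-8)


@pytest.fixture(scope="session")
def generic_target(generic_grid) -> SpeedTarget:
    return SpeedTarget.for_continuous(10.0, generic_grid)


@pytest.fixture(scope="session")
def spongy_target() -> SpeedTarget:
    return SpeedTarget.for_discrete(0.5)
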