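import numpy as np
import pytest

from subtherm import AcquisitionParams, PhantomSpec, VoxelGrid, refine_grid


@pytest.fixture
def params_15t() -> AcquisitionParams:
    """1.5 T protocol: TE 15 ms, water PRFS coefficient."""
    return AcquisitionParams(b0=1.5, te=0.015)


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(shape=(8, 8, 4), spacing=(2.3, 2.3, 4.5))


@pytest.fixture
def small_subgrid(small_grid):
    return refine_grid(small_grid, 2)


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Down-scaled phantom for fast correction tests (same voxel geometry)."""
    return PhantomSpec(shape=(24, 24, 3), line_len=4, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
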