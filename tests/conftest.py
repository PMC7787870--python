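import numpy as np
import pytest

from hmrfmix import EffectSizeDistribution, SummaryData, VoxelLattice


@pytest.fixture
def edge_lattice():
    """1x1x2 lattice: two voxels, one face-adjacent pair."""
    return VoxelLattice.full((1, 1, 2))


@pytest.fixture
def square_lattice():
    """2x2x1 lattice: four voxels, four face-adjacent pairs."""
    return VoxelLattice.full((2, 2, 1))


@pytest.fixture
def line3_lattice():
    """1x1x3 chain of three voxels."""
    return VoxelLattice.full((1, 1, 3))


@pytest.fixture
def meta_normal():
    """Normal-family metadata with c_n = 0.2 (n1 = n2 = 50)."""
    return SummaryData(y=np.zeros(1), n1=50, n2=50, family="normal")


@pytest.fixture
def meta_t():
    """t-family metadata with c_n = 0.2, df = 98."""
    return SummaryData(y=np.zeros(1), n1=50, n2=50, family="t")


@pytest.fixture
def g_two_points():
    """Equal mass at 0.2 and 0.4."""
    return EffectSizeDistribution(np.array([0.2, 0.4]), np.array([0.5, 0.5]))
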