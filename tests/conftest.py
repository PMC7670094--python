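"""Shared fixtures: chromophore tables, a small path-length lookup table and
a small noise-free dataset, all generated at test time."""

import numpy as np
import pytest

from oxidrs.dataset import ParameterDistributions, generate_dataset
from oxidrs.forward import default_wavelength_grid
from oxidrs.montecarlo import ProbeGeometry, build_table
from oxidrs.noise import NoiseSpec
from oxidrs.tissue_optics import ChromophoreTable, TissueParams


@pytest.fixture(scope="session")
def chromo():
    return ChromophoreTable.default()


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def grid():
    return default_wavelength_grid()


@pytest.fixture(scope="session")
def dists():
    return ParameterDistributions.default()


@pytest.fixture(scope="session")
def small_table(geometry, dists, grid):
    """A coarse lookup table covering the default parameter support."""
    m_lo, m_hi = dists.musp_support(grid)
    t_axis = np.linspace(0.04, 0.16, 3)
    m_axis = np.exp(np.linspace(np.log(m_lo * 0.95), np.log(m_hi * 1.05), 5))
    return build_table(t_axis, m_axis, geometry, 30_000, seed=11)


@pytest.fixture(scope="session")
def typical_params():
    return TissueParams(
        t_epi=0.1, f_mel=0.02, beta_mel=3.0, f_bcaro=0.002, f_lyco=0.002,
        f_blood=0.01, r_blood=0.2, s_o2=0.7, delta_o2=0.1, f_met=0.01,
        d_avg=0.02, r_d=0.3, alpha=2.5, beta=1.5, gamma=0.2)


@pytest.fixture(scope="session")
def tiny_clean_dataset(small_table, dists, grid):
    """2000 noise-free records for recovery and exclusion tests."""
    return generate_dataset(2000, dists, small_table, grid,
                            NoiseSpec.disabled(), seed=55)
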