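"""Shared fixtures: the heavier Monte-Carlo stacks are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from smoct import studies


@pytest.fixture(scope="session")
def iid_stack():
    """10^4 voxels x 50 equal-amplitude scatterers, 100 independent screens."""
    return studies.iid_speckle_stack(10_000, 50, 100, seed=1)


@pytest.fixture(scope="session")
def screened_stack():
    """Diffuser-driven voxel stack: 2x10^4 voxels, offsets 3x the corr length."""
    return studies.screened_speckle_stack(
        n_voxels=20_000, n_per_voxel=50, m_frames=100, seed=1
    )


@pytest.fixture(scope="session")
def rayleigh_pixels():
    """10^5 fully developed single-frame voxel magnitudes (N=50)."""
    return studies.iid_speckle_stack(100_000, 50, 1, seed=2)[0]


@pytest.fixture(scope="session")
def gns_stack():
    """Poisson(12) scatterers per voxel, 2x10^4 voxels, 100 modulated frames."""
    return studies.iid_speckle_stack(20_000, None, 100, seed=5, poisson_lambda=12.0)


@pytest.fixture(scope="session")
def gns_stack_conventional():
    return studies.iid_speckle_stack(
        20_000, None, 100, seed=5, poisson_lambda=12.0, modulated=False
    )


@pytest.fixture(scope="session")
def dispersion_recovery():
    """20 random-beta noiseless recovery trials."""
    return studies.dispersion_study(seed=3)


@pytest.fixture(scope="session")
def gap_by_seed():
    """Minimum detectable gap, SM vs conventional, over 5 phantom seeds."""
    return studies.gap_direction_over_seeds(range(5))


@pytest.fixture(scope="session")
def attenuation_result():
    return studies.attenuation_study(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
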