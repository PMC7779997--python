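"""Shared fixtures: optical properties and Monte Carlo photon histories.

The transport runs are session-scoped so one simulation serves every test
module that needs a history; the large run used by the stochastic
validation tests is only built when a test actually requests it.
"""

from __future__ import annotations

import pytest

from dcsmc.optics import OpticalProperties
from dcsmc.transport import LayeredGeometry, McConfig, simulate

#: Seed feeding every fixture RNG in the suite.
SUITE_SEED = 20260930


@pytest.fixture(scope="session")
def forehead_props() -> OpticalProperties:
    """Bulk properties assumed by the analytical fits at 850 nm."""
    return OpticalProperties(wavelength_nm=850.0, mu_a=0.015, mu_sp=0.85, n=1.37)


@pytest.fixture(scope="session")
def slab_geometry() -> LayeredGeometry:
    return LayeredGeometry(kind="slab", n_fine_layers=21, mu_s=0.85)


@pytest.fixture(scope="session")
def slab_history_small(slab_geometry):
    """Quick 4e5-photon slab history for unit tests."""
    return simulate(slab_geometry,
                    McConfig(photons_launched=400_000, rng_seed=SUITE_SEED % 2**31))


@pytest.fixture(scope="session")
def slab_history_large(slab_geometry):
    """Production-scale 1e7-photon slab history for the stochastic checks."""
    return simulate(slab_geometry,
                    McConfig(photons_launched=10_000_000, rng_seed=101))
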