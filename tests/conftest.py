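"""Shared fixtures: session-scoped transport runs over the analysis bands.

The heavy Monte Carlo work is done once per session at desk-scale photon
budgets and reused by the spectrum, depth, probe and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgsim.mc_transport import MCConfig
from ppgsim.ppg_spectra import simulate_condition
from ppgsim.skin_models import compressed_model, reference_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: desk-scale photon budget for the shared condition runs
FIXTURE_PHOTONS = 30_000
#: wavelengths covering the depth analysis (green) plus all three ratio bands
REF_WAVELENGTHS = [500.0, 530.0, 550.0, 577.0, 660.0, 700.0, 800.0, 840.0]
COMP_WAVELENGTHS = [530.0, 550.0, 577.0, 660.0, 700.0, 800.0, 840.0]


@pytest.fixture(scope="session")
def ref_run():
    """Reference-skin condition run shared across the suite."""
    return simulate_condition(
        reference_model(), REF_WAVELENGTHS, MCConfig(n_photons=FIXTURE_PHOTONS, seed=1)
    )


@pytest.fixture(scope="session")
def comp_run():
    """Compressed-skin condition run shared across the suite."""
    return simulate_condition(
        compressed_model(), COMP_WAVELENGTHS, MCConfig(n_photons=FIXTURE_PHOTONS, seed=2)
    )


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def comp_model():
    return compressed_model()
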