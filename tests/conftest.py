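"""Shared fixtures and hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def amex_bm_baseline():
    """Axolotl normal-diffusion parameter set at the reference h_p."""
    from segclock.experiments import species_baseline

    return species_baseline("ambystoma_mexicanum", "normal", h_p=15.0)


@pytest.fixture(scope="session")
def amex_bm_solution(amex_bm_baseline):
    """One full-span reference integration, reused across tests."""
    from segclock.clock_dde import integrate

    return integrate(amex_bm_baseline)
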