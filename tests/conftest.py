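"""Shared fixtures: small architectures and shortened assay protocols.

Everything is generated programmatically; the scaled-down architecture
(N=2000, M=45, L=10) and mini protocol keep simulation-backed tests fast
while preserving the blocked-fusion regime of the full-scale network.
"""

import math

import pytest

from glut4queue import ProtocolConfig, SystemParameters
from glut4queue.fitting import FitBounds, ParameterBound


@pytest.fixture(scope="session")
def small_params():
    """Tiny network for event-level tests."""
    return SystemParameters(mu_S=1.0, mu_M=2.0, mu_F=3.0, mu_P=1.5, N=60, M=5, L=4,
                            active_prob={0.0: 0.5, 100.0: 1.0})


@pytest.fixture(scope="session")
def scaled_params():
    """Scaled-down version of the adipocyte network (N=2000, M=45, L=10).

    Rates keep the fusion sites as the bottleneck at stimulated insulin, as
    in the full-scale fitted network, and the uptake assay reaches its
    plateau within the shortened grid at both insulin levels.
    """
    return SystemParameters(mu_S=0.12, mu_M=2.0, mu_F=2.4, mu_P=0.25,
                            N=2000, M=45, L=10,
                            active_prob={0.0: 0.45, 100.0: 0.9})


@pytest.fixture(scope="session")
def mini_protocol():
    """Shortened assay suite for the scaled-down network: 1 transition level
    and 2 uptake levels, warm-up/equilibration 20 min (relaxation times of
    the scaled network are a few minutes), uptake sampled to its plateau."""
    return ProtocolConfig(warm_up=20.0, equilibration=20.0,
                          transition_times=(0, 1, 2, 5, 10, 15, 20),
                          uptake_times=(0, 2, 5, 10, 20, 40, 70, 120),
                          transition_levels=(100.0,),
                          uptake_levels=(0.0, 100.0),
                          reference_insulin=100.0)


@pytest.fixture(scope="session")
def scaled_bounds():
    """Fit bounds for the scaled-down architecture (N held fixed)."""
    return FitBounds({
        "mu_S": ParameterBound(1e-6, math.inf, 0.02),
        "mu_M": ParameterBound(1e-6, math.inf, 0.3),
        "mu_F": ParameterBound(1e-6, math.inf, 0.05),
        "mu_P": ParameterBound(1e-6, math.inf, 0.008),
        "p(0)": ParameterBound(0.01, 1.0, 0.02),
        "p(100)": ParameterBound(0.01, 1.0, 0.02),
    })
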