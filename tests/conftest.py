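"""Shared fixtures: experiment conditions, tensors, reduced-resolution model
configuration and a compact fixture vesicle distribution.

The model configuration and distribution used here are deliberately
smaller than the library defaults (fewer powder orientations, Legendre
orders and radius support points); forward-model accuracy at this
resolution is itself asserted by the convergence and oracle tests.
"""

import numpy as np
import pytest

from codexfit import (
    CSATensor,
    ExperimentConditions,
    SingleVesicleModelConfig,
    celsius_to_kelvin,
    lognormal_radius_distribution,
)


@pytest.fixture(scope="session")
def cond55():
    """55 °C aqueous NaCl suspension spun at 4 kHz, 162.0 MHz ³¹P."""
    return ExperimentConditions(
        temperature=celsius_to_kelvin(55.0),
        viscosity=5.5e-4,
        mas_rate=4000.0,
        larmor_frequency=162.0,
        n_pi_pulses=3,
    )


@pytest.fixture(scope="session")
def cond2k(cond55):
    """Slow-spinning (2 kHz) conditions for sideband manifolds."""
    return ExperimentConditions(
        temperature=cond55.temperature,
        viscosity=cond55.viscosity,
        mas_rate=2000.0,
        larmor_frequency=162.0,
        n_pi_pulses=3,
    )


@pytest.fixture(scope="session")
def csa_pe():
    return CSATensor(delta_iso=0.05, delta_cs=20.8, label="PE")


@pytest.fixture(scope="session")
def csa_pg():
    return CSATensor(delta_iso=0.49, delta_cs=19.2, label="PG")


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-resolution model config reused across tests (cache-friendly)."""
    return SingleVesicleModelConfig(
        grid_size=400,
        legendre_truncation=30,
        integration_steps_per_rotor_period=32,
        displacement_quadrature_size=36,
    )


@pytest.fixture(scope="session")
def small_dist():
    """Compact lognormal fixture distribution (20 radius support points)."""
    return lognormal_radius_distribution(
        median=150e-9, geometric_sd=1.5, n_points=20, r_min=20e-9, r_max=1000e-9
    )


@pytest.fixture(scope="session")
def rotor_multiples():
    return np.array([1, 2, 4, 8, 16, 32, 64, 128])


@pytest.fixture(scope="session")
def mixing_times(cond55, rotor_multiples):
    return rotor_multiples * cond55.rotor_period
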