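"""Recoupled-phase physics and the single-vesicle decay model."""

import math

import numpy as np
import pytest

from codexfit import (
    CSATensor,
    OrientationGrid,
    SingleVesicleModelConfig,
    angular_diffusion_coefficient,
    recoupled_phase,
    rotational_correlation_time,
    single_vesicle_codex_decay,
    sphere_propagator_moment,
)
from codexfit.spin import orientation_correlation_coefficients


class TestRecoupledPhase:
    def test_rotor_axis_orientation_accumulates_no_phase(self, csa_pe, cond55):
        """With the unique axis on the rotor axis the MAS modulation vanishes
        (the static second-rank term is zero at the magic angle)."""
        assert recoupled_phase(0.0, 0.7, csa_pe, cond55) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("beta,gamma", [(0.4, 0.0), (1.0, 1.3), (2.2, 4.0)])
    def test_linearity_in_anisotropy(self, beta, gamma, csa_pe, cond55):
        doubled = CSATensor(csa_pe.delta_iso, 2 * csa_pe.delta_cs, label="PE")
        p1 = recoupled_phase(beta, gamma, csa_pe, cond55)
        p2 = recoupled_phase(beta, gamma, doubled, cond55)
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_azimuthal_average_vanishes(self, csa_pe, cond55):
        """The gamma-average of the phase is zero at any beta: checked against
        a fine-grid numerical average."""
        gamma = np.linspace(0.0, 2 * math.pi, 720, endpoint=False)
        for beta in (0.5, 1.0, 1.4):
            phases = [recoupled_phase(beta, g, csa_pe, cond55) for g in gamma]
            scale = np.abs(phases).max()
            assert abs(np.mean(phases)) < 1e-9 * max(scale, 1.0)

    def test_rejects_non_finite_angles(self, csa_pe, cond55):
        with pytest.raises(ValueError):
            recoupled_phase(math.nan, 0.0, csa_pe, cond55)


class TestSpherePropagator:
    def test_probability_conservation_l0(self):
        assert sphere_propagator_moment(0, 12.3, 100.0) == 1.0

    def test_delta_initial_condition(self):
        assert sphere_propagator_moment(7, 0.0, 55.0) == 1.0

    def test_l2_decay_value(self):
        # exp(-2*3*0.1) = exp(-0.6)
        assert sphere_propagator_moment(2, 0.1, 1.0) == pytest.approx(0.5488, abs=1e-4)

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            sphere_propagator_moment(2, -1.0, 1.0)


class TestAngularDiffusion:
    def test_pure_tumbling_rate(self, cond55):
        # kB*328.15K / (8 pi * 5.5e-4 Pa s * (100 nm)^3)
        assert angular_diffusion_coefficient(100e-9, 0.0, cond55) == pytest.approx(
            327.8, abs=0.1
        )

    def test_lateral_term_adds_d_over_r_squared(self, cond55):
        base = angular_diffusion_coefficient(100e-9, 0.0, cond55)
        combined = angular_diffusion_coefficient(100e-9, 1e-12, cond55)
        assert combined - base == pytest.approx(100.0, rel=1e-9)

    @pytest.mark.parametrize("r,d_lat", [(50e-9, 0.0), (100e-9, 1e-12), (400e-9, 8e-12)])
    def test_consistency_with_correlation_time(self, r, d_lat, cond55):
        """6 x d_ang must equal 1/tau_c for identical inputs."""
        d_ang = angular_diffusion_coefficient(r, d_lat, cond55)
        tau_c = rotational_correlation_time(r, d_lat, cond55)
        assert 6.0 * d_ang == pytest.approx(1.0 / tau_c, rel=1e-12)

    def test_rejects_nonpositive_radius(self, cond55):
        with pytest.raises(ValueError):
            angular_diffusion_coefficient(0.0, 1e-12, cond55)


class TestOrientationGrid:
    def test_second_moment_coverage(self):
        grid = OrientationGrid.fibonacci(2000)
        p2 = 0.5 * (3 * np.cos(grid.beta) ** 2 - 1)
        assert abs(np.sum(grid.weights * p2)) < 1e-3
        assert grid.weights.sum() == pytest.approx(1.0)


class TestSingleVesicleDecay:
    def test_zero_mixing_time_gives_unity(self, csa_pe, cond55, fast_config):
        tm = np.array([0.0, 2.5e-4, 1e-3])
        curve = single_vesicle_codex_decay(150e-9, 3e-12, csa_pe, cond55, tm, fast_config)
        assert curve.signal[0] == 1.0

    def test_frozen_reorientation_keeps_full_signal(self, csa_pe, fast_config, cond55):
        """No lateral diffusion and (effectively) infinite viscosity: no
        reorientation pathway, E stays at 1."""
        from codexfit import ExperimentConditions

        frozen = ExperimentConditions(
            temperature=cond55.temperature, viscosity=1e12,
            mas_rate=cond55.mas_rate, larmor_frequency=cond55.larmor_frequency,
            n_pi_pulses=cond55.n_pi_pulses,
        )
        tm = np.array([2.5e-4, 1e-3, 8e-3])
        curve = single_vesicle_codex_decay(150e-9, 0.0, csa_pe, frozen, tm, fast_config)
        assert np.allclose(curve.signal, 1.0, atol=1e-6)

    def test_bounded_and_monotone(self, csa_pe, cond55, fast_config, mixing_times):
        curve = single_vesicle_codex_decay(
            200e-9, 5e-12, csa_pe, cond55, mixing_times, fast_config
        )
        assert np.all(curve.signal <= 1.0 + 1e-9)
        assert np.all(curve.signal >= -1.0 - 1e-9)
        assert np.all(np.diff(curve.signal) <= fast_config.tolerance)

    def test_long_time_plateau_is_powder_coherence(self, csa_pe, cond55, fast_config):
        """The t_m -> infinity plateau equals |<exp(i Phi)>|^2 over the powder,
        evaluated here by direct averaging over an independent random
        orientation sample."""
        rng = np.random.default_rng(11)
        v = rng.normal(size=(40000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        beta = np.arccos(np.clip(v[:, 2], -1, 1))
        gamma = np.arctan2(v[:, 1], v[:, 0])
        phases = np.array(
            [recoupled_phase(b, g, csa_pe, cond55) for b, g in zip(beta[:4000], gamma[:4000])]
        )
        plateau_direct = abs(np.mean(np.exp(1j * phases))) ** 2
        a_l, _ = orientation_correlation_coefficients(csa_pe, cond55, fast_config)
        assert a_l[0] == pytest.approx(plateau_direct, abs=5e-3)
        tm = np.array([0.5, 1.0])  # seconds: fully decorrelated
        curve = single_vesicle_codex_decay(150e-9, 5e-12, csa_pe, cond55, tm, fast_config)
        assert curve.signal[-1] == pytest.approx(a_l[0], abs=1e-6)

    def test_truncation_tail_small_and_coefficients_positive(
        self, csa_pe, cond55, fast_config
    ):
        a_l, tail = orientation_correlation_coefficients(csa_pe, cond55, fast_config)
        assert abs(tail) < fast_config.tolerance
        assert np.all(a_l > -1e-6)

    def test_refinement_convergence(self, csa_pe, cond55, fast_config, cond2k):
        """Doubling powder grid, Legendre truncation and time resolution moves
        E by less than the configured tolerance."""
        fine = SingleVesicleModelConfig(
            grid_size=2 * fast_config.grid_size,
            legendre_truncation=2 * fast_config.legendre_truncation,
            integration_steps_per_rotor_period=2
            * fast_config.integration_steps_per_rotor_period,
            displacement_quadrature_size=2 * fast_config.displacement_quadrature_size,
        )
        tm = np.array([1, 4, 16, 64]) * cond55.rotor_period
        coarse = single_vesicle_codex_decay(200e-9, 5e-12, csa_pe, cond55, tm, fast_config)
        refined = single_vesicle_codex_decay(200e-9, 5e-12, csa_pe, cond55, tm, fine)
        # 0.2% absolute: the powder-grid discretization floor at 400 points
        assert np.max(np.abs(coarse.signal - refined.signal)) < 0.002

    def test_rejects_unsorted_mixing_times(self, csa_pe, cond55, fast_config):
        with pytest.raises(ValueError):
            single_vesicle_codex_decay(
                150e-9, 3e-12, csa_pe, cond55, [1e-3, 5e-4], fast_config
            )

    def test_tumbling_switch_slows_decay(self, csa_pe, cond55, fast_config):
        """Disabling the tumbling term in the mixing propagator leaves only
        lateral diffusion and must slow the decay for a small vesicle."""
        no_tumble = SingleVesicleModelConfig(
            grid_size=fast_config.grid_size,
            legendre_truncation=fast_config.legendre_truncation,
            integration_steps_per_rotor_period=fast_config.integration_steps_per_rotor_period,
            displacement_quadrature_size=fast_config.displacement_quadrature_size,
            include_tumbling=False,
        )
        tm = np.array([1, 8, 64]) * cond55.rotor_period
        with_t = single_vesicle_codex_decay(100e-9, 1e-12, csa_pe, cond55, tm, fast_config)
        without = single_vesicle_codex_decay(100e-9, 1e-12, csa_pe, cond55, tm, no_tumble)
        assert np.all(without.signal >= with_t.signal - 1e-9)
        assert without.signal[1] > with_t.signal[1]
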