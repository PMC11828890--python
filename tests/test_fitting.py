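"""D_lat estimation, bootstrap CIs and mono-exponential relaxation fits."""

import numpy as np
import pytest

from codexfit import (
    CodexDecayDataset,
    CodexDiffusionFitter,
    RelaxationDataset,
    ci95_bootstrap,
    fit_dlat,
    fit_t1_inversion_recovery,
    fit_t2_echo,
    synth_codex_dataset,
    synth_relaxation,
    NoiseSpec,
)


class TestDlatRecovery:
    @pytest.mark.parametrize("d_true_1e12", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_noiseless_recovery_within_one_percent(
        self, d_true_1e12, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        d_true = d_true_1e12 * 1e-12
        data = synth_codex_dataset(
            d_true, small_dist, csa_pe, cond55, mixing_times, NoiseSpec(), fast_config
        )
        result = fit_dlat(data, small_dist, csa_pe, cond55, fast_config)
        assert result.converged
        assert result.d_lat == pytest.approx(d_true, rel=0.01)
        assert result.residual_rms < 1e-6

    def test_amplitude_recovered(self, small_dist, csa_pe, cond55, fast_config, mixing_times):
        data = synth_codex_dataset(
            4e-12, small_dist, csa_pe, cond55, mixing_times, NoiseSpec(),
            fast_config, amplitude=0.83,
        )
        result = fit_dlat(data, small_dist, csa_pe, cond55, fast_config)
        assert result.amplitude == pytest.approx(0.83, abs=0.01)
        assert result.d_lat == pytest.approx(4e-12, rel=0.01)

    def test_flat_data_flagged_unconverged(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        data = CodexDecayDataset(
            label="PE", mixing_times=mixing_times, intensities=np.ones_like(mixing_times)
        )
        result = fit_dlat(data, small_dist, csa_pe, cond55, fast_config)
        assert not result.converged
        assert "lower" in result.diagnostics

    def test_requires_four_points(self, small_dist, csa_pe, cond55, fast_config):
        data = CodexDecayDataset(
            label="PE",
            mixing_times=np.array([2.5e-4, 5e-4, 1e-3]),
            intensities=np.array([0.9, 0.8, 0.7]),
        )
        with pytest.raises(ValueError, match="at least 4"):
            fit_dlat(data, small_dist, csa_pe, cond55, fast_config)

    def test_noisy_precision_bound(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        """With sigma = 0.02 on 8 mixing times the median relative error over
        100 replicates stays under 15%."""
        d_true = 5.5e-12
        errors = []
        for rep in range(100):
            data = synth_codex_dataset(
                d_true, small_dist, csa_pe, cond55, mixing_times,
                NoiseSpec(sd=0.02, seed=1000 + rep), fast_config,
            )
            result = fit_dlat(data, small_dist, csa_pe, cond55, fast_config)
            errors.append(abs(result.d_lat - d_true) / d_true)
        assert np.median(errors) < 0.15

    def test_objective_not_worse_than_grid_start(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        """The refined solution must not regress behind the coarse-grid start
        (descent contract of the trust-region solver)."""
        data = synth_codex_dataset(
            3e-12, small_dist, csa_pe, cond55, mixing_times,
            NoiseSpec(sd=0.03, seed=7), fast_config,
        )
        est = CodexDiffusionFitter(
            distribution=small_dist, csa=csa_pe, conditions=cond55,
            model_config=fast_config,
        )
        est.fit(data.mixing_times, data.intensities)
        sse_final = float(np.sum(est.result_.residuals ** 2))
        sse_grid = min(
            float(np.sum((est._best_amplitude(data.intensities, m) * m - data.intensities) ** 2))
            for m in est._grid_curves_.values()
        )
        assert sse_final <= sse_grid + 1e-12

    def test_sklearn_interface(self, small_dist, csa_pe, cond55, fast_config, mixing_times):
        data = synth_codex_dataset(
            2e-12, small_dist, csa_pe, cond55, mixing_times, NoiseSpec(), fast_config
        )
        est = CodexDiffusionFitter(
            distribution=small_dist, csa=csa_pe, conditions=cond55,
            model_config=fast_config,
        )
        cloned_params = est.get_params()
        assert cloned_params["model_config"] is fast_config
        est.fit(data.mixing_times.reshape(-1, 1), data.intensities)
        pred = est.predict(data.mixing_times.reshape(-1, 1))
        assert pred == pytest.approx(data.intensities, abs=1e-5)


class TestBootstrap:
    def test_zero_residual_data_gives_degenerate_ci(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        data = synth_codex_dataset(
            4e-12, small_dist, csa_pe, cond55, mixing_times, NoiseSpec(), fast_config
        )
        est = CodexDiffusionFitter(
            distribution=small_dist, csa=csa_pe, conditions=cond55,
            model_config=fast_config,
        )
        est.fit(data.mixing_times, data.intensities)
        lo, hi = est.bootstrap_ci(data.mixing_times, data.intensities, n_boot=60, seed=0)
        assert (hi - lo) / est.d_lat_ < 1e-3

    def test_fixed_seed_reproducible(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        data = synth_codex_dataset(
            4e-12, small_dist, csa_pe, cond55, mixing_times,
            NoiseSpec(sd=0.02, seed=3), fast_config,
        )
        fit = fit_dlat(data, small_dist, csa_pe, cond55, fast_config)
        ci_a = ci95_bootstrap(
            data, fit, small_dist, csa_pe, cond55, fast_config, n_boot=80, seed=42
        )
        ci_b = ci95_bootstrap(
            data, fit, small_dist, csa_pe, cond55, fast_config, n_boot=80, seed=42
        )
        assert ci_a == ci_b

    def test_ci_brackets_estimate_and_small_nboot_warns(
        self, small_dist, csa_pe, cond55, fast_config, mixing_times
    ):
        data = synth_codex_dataset(
            4e-12, small_dist, csa_pe, cond55, mixing_times,
            NoiseSpec(sd=0.02, seed=9), fast_config,
        )
        est = CodexDiffusionFitter(
            distribution=small_dist, csa=csa_pe, conditions=cond55,
            model_config=fast_config,
        )
        est.fit(data.mixing_times, data.intensities)
        with pytest.warns(UserWarning, match="n_boot"):
            lo, hi = est.bootstrap_ci(data.mixing_times, data.intensities, n_boot=49, seed=1)
        assert lo <= est.d_lat_ <= hi


class TestInversionRecovery:
    delays = np.array([0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])

    def test_recovers_t1(self):
        data = synth_relaxation("inversion_recovery", 1.35, self.delays)
        result = fit_t1_inversion_recovery(data)
        assert result.converged
        assert result.time_constant == pytest.approx(1.35, rel=0.01)

    def test_full_inversion_at_zero_delay(self):
        data = synth_relaxation("inversion_recovery", 1.35, np.array([0.0, 0.5, 1, 2, 6]))
        assert data.intensities[0] == pytest.approx(-1.0)

    def test_intensity_scale_invariance(self):
        data = synth_relaxation("inversion_recovery", 0.8, self.delays, m0=1.0)
        scaled = RelaxationDataset(
            delays=data.delays, intensities=3.7 * data.intensities,
            mode="inversion_recovery",
        )
        a = fit_t1_inversion_recovery(data)
        b = fit_t1_inversion_recovery(scaled)
        assert b.time_constant == pytest.approx(a.time_constant, rel=1e-6)
        assert b.m0 == pytest.approx(3.7 * a.m0, rel=1e-6)

    def test_mode_mismatch_rejected(self):
        data = synth_relaxation("echo_decay", 0.0035, np.array([1e-3, 2e-3, 4e-3, 8e-3]))
        with pytest.raises(ValueError):
            fit_t1_inversion_recovery(data)


class TestEchoDecay:
    delays = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0]) * 1e-3

    def test_recovers_t2(self):
        data = synth_relaxation("echo_decay", 3.5e-3, self.delays)
        result = fit_t2_echo(data)
        assert result.time_constant == pytest.approx(3.5e-3, rel=0.01)

    def test_e_folding_point(self):
        data = synth_relaxation("echo_decay", 2e-3, np.array([0.0, 2e-3]))
        assert data.intensities[1] == pytest.approx(np.exp(-1.0))

    def test_matches_log_linear_regression(self):
        data = synth_relaxation("echo_decay", 3.5e-3, self.delays)
        slope, _ = np.polyfit(data.delays, np.log(data.intensities), 1)
        result = fit_t2_echo(data)
        assert result.time_constant == pytest.approx(-1.0 / slope, rel=0.01)

    def test_single_point_rejected(self):
        data = RelaxationDataset(
            delays=np.array([1e-3]), intensities=np.array([0.7]), mode="echo_decay"
        )
        with pytest.raises(ValueError):
            fit_t2_echo(data)
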