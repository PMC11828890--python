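"""Estimation of D_lat and relaxation time constants from measured decays.

The central estimator, :class:`CodexDiffusionFitter`, is scikit-learn
shaped: ``fit(X, y)`` takes mixing times and normalized CODEX
intensities, finds the lateral diffusion coefficient (and a free
amplitude) by bounded nonlinear least squares against the vesicle-
ensemble forward model, and exposes the result through trailing-
underscore attributes plus a :class:`DlatFitResult`.  A residual
bootstrap supplies the 95% confidence interval.

Mono-exponential inversion-recovery (T1) and echo-decay (T2) fits follow
the same estimator pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, t as student_t
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import CSATensor, ExperimentConditions
from .ensemble import (
    VesicleSizeDistribution,
    default_tau_echo,
    ensemble_codex_decay,
)
from .spin import SingleVesicleModelConfig

__all__ = [
    "CodexDecayDataset",
    "RelaxationDataset",
    "DlatFitResult",
    "RelaxationFitResult",
    "CodexDiffusionFitter",
    "InversionRecoveryFitter",
    "EchoDecayFitter",
    "fit_dlat",
    "ci95_bootstrap",
    "fit_t1_inversion_recovery",
    "fit_t2_echo",
]


@dataclass
class CodexDecayDataset:
    """Per-resonance CODEX decay data.

    ``mixing_times`` in s (non-negative, strictly increasing),
    ``intensities`` normalized so the earliest point is close to the
    amplitude, optional per-point uncertainties.
    """

    label: str
    mixing_times: np.ndarray
    intensities: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mixing_times.shape != self.intensities.shape:
            raise ValueError("mixing_times and intensities must have equal length")
        if np.any(self.mixing_times < 0):
            raise ValueError("mixing times must be non-negative")
        if self.mixing_times.size > 1 and np.any(np.diff(self.mixing_times) <= 0):
            raise ValueError("mixing times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.mixing_times.shape:
                raise ValueError("uncertainties must match mixing_times in length")


@dataclass
class RelaxationDataset:
    """Delays and intensities from an inversion-recovery or echo train."""

    delays: np.ndarray
    intensities: np.ndarray
    mode: str = "inversion_recovery"

    _MODES = ("inversion_recovery", "echo_decay")

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if self.delays.size > 1 and np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be increasing")


@dataclass
class DlatFitResult:
    """Fitted lateral diffusion coefficient with diagnostics.

    ``d_lat`` and the CI bounds in m²/s (``ci95_*`` are NaN until a
    bootstrap has been run).
    """

    d_lat: float
    amplitude: float
    ci95_low: float = math.nan
    ci95_high: float = math.nan
    residual_rms: float = math.nan
    converged: bool = True
    diagnostics: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def d_lat_1e12(self) -> float:
        """D_lat in the reporting unit 10⁻¹² m²/s."""
        return self.d_lat * 1e12


@dataclass
class RelaxationFitResult:
    """Mono-exponential relaxation fit result (T1 or T2), s."""

    time_constant: float
    m0: float
    inversion_factor: float = math.nan
    converged: bool = True
    diagnostics: str = ""


class CodexDiffusionFitter(RegressorMixin, BaseEstimator):
    """Fit D_lat from a CODEX decay against the vesicle-ensemble model.

    Minimizes ``sum (E_obs(t_m) - A * E_pop(t_m; D))^2`` over the
    diffusion coefficient D (bounded, optimized in log space) and a free
    amplitude A in (0, amplitude_max].  The amplitude absorbs the
    per-resonance normalization of the data (experimental series are
    commonly normalized to one resonance, so the absolute scale is not
    1); the infinite-time plateau comes from the forward model's powder
    average and is not a free parameter.

    The optimizer starts from the best point of a log-spaced coarse grid
    over D; forward curves on the grid are cached for reuse by the
    bootstrap.

    Parameters
    ----------
    distribution : VesicleSizeDistribution
        Number-weighted vesicle radius distribution (DLS).
    csa : CSATensor
        Motionally averaged ³¹P tensor of the resonance.
    conditions : ExperimentConditions
        Temperature, viscosity, MAS rate, Larmor frequency, pulse count.
    model_config : SingleVesicleModelConfig, optional
        Numerical resolution of the forward model.
    tau_echo : float, optional
        Total CSA recoupling duration, s.  Default: two periods of
        ``n_pi_pulses * t_r / 2`` each.
    d_bounds : (float, float)
        Search bounds for D_lat, m²/s.
    grid_points : int
        Size of the log-spaced coarse start grid over D.
    amplitude_max : float
        Upper bound for the free amplitude.
    n_boot, seed : int
        If ``n_boot > 0``, a residual bootstrap with this seed runs at
        fit time and fills the 95% CI.

    Attributes
    ----------
    d_lat_ : float
        Fitted lateral diffusion coefficient, m²/s.
    amplitude_ : float
        Fitted amplitude.
    ci95_ : tuple of float
        Bootstrap 95% CI (NaN, NaN) unless a bootstrap has been run.
    converged_ : bool
    result_ : DlatFitResult
    """

    def __init__(
        self,
        distribution: VesicleSizeDistribution | None = None,
        csa: CSATensor | None = None,
        conditions: ExperimentConditions | None = None,
        model_config: SingleVesicleModelConfig | None = None,
        tau_echo: float | None = None,
        d_bounds: tuple[float, float] = (1e-14, 1e-10),
        grid_points: int = 12,
        amplitude_max: float = 1.2,
        n_boot: int = 0,
        seed: int | None = None,
    ):
        self.distribution = distribution
        self.csa = csa
        self.conditions = conditions
        self.model_config = model_config
        self.tau_echo = tau_echo
        self.d_bounds = d_bounds
        self.grid_points = grid_points
        self.amplitude_max = amplitude_max
        self.n_boot = n_boot
        self.seed = seed

    # -- internal ---------------------------------------------------------

    def _resolve(self):
        if self.distribution is None or self.csa is None or self.conditions is None:
            raise ValueError("distribution, csa and conditions are required")
        config = self.model_config or SingleVesicleModelConfig()
        tau_echo = (
            self.tau_echo
            if self.tau_echo is not None
            else default_tau_echo(self.conditions)
        )
        return config, tau_echo

    def _model(self, tm: np.ndarray, d: float) -> np.ndarray:
        config, tau_echo = self._resolve()
        return ensemble_codex_decay(
            self.distribution, d, self.csa, self.conditions, tm,
            config=config, tau_echo=tau_echo,
        ).signal

    @staticmethod
    def _validate_xy(X, y):
        tm = np.asarray(X, dtype=float)
        if tm.ndim == 2:
            if tm.shape[1] != 1:
                raise ValueError("X must be mixing times of shape (n,) or (n, 1)")
            tm = tm[:, 0]
        y = np.asarray(y, dtype=float)
        if tm.shape != y.shape:
            raise ValueError("X and y must have equal length")
        if tm.size < 4:
            raise ValueError("need at least 4 mixing-time points")
        if np.any(tm < 0) or np.any(np.diff(tm) <= 0):
            raise ValueError("mixing times must be non-negative and strictly increasing")
        return tm, y

    def _best_amplitude(self, y: np.ndarray, m: np.ndarray) -> float:
        denom = float(m @ m)
        a = float(y @ m) / denom if denom > 0 else 1.0
        return float(np.clip(a, 1e-6, self.amplitude_max))

    def _solve(self, tm: np.ndarray, y: np.ndarray, d0: float, a0: float):
        lo, hi = self.d_bounds

        def residual(x):
            d, a = 10.0 ** x[0], x[1]
            return a * self._model(tm, d) - y

        sol = least_squares(
            residual,
            x0=[math.log10(d0), a0],
            bounds=([math.log10(lo), 1e-6], [math.log10(hi), self.amplitude_max]),
            xtol=1e-10,
            ftol=1e-12,
        )
        return 10.0 ** sol.x[0], float(sol.x[1]), sol

    def _leverages(self, tm: np.ndarray) -> np.ndarray:
        """Hat-matrix diagonal of the linearized model at the point estimate.

        Invariant under reparametrization of (D, A); used to rescale
        residuals for the bootstrap.
        """
        eps = 1e-3
        m0 = self._model(tm, self.d_lat_)
        m1 = self._model(tm, self.d_lat_ * (1.0 + eps))
        jac = np.column_stack(
            [self.amplitude_ * (m1 - m0) / (self.d_lat_ * eps), m0]
        )
        q, _ = np.linalg.qr(jac)
        return np.sum(q**2, axis=1)

    # -- API --------------------------------------------------------------

    def fit(self, X, y):
        """Fit the decay.  X: mixing times (s), y: normalized intensities."""
        tm, y = self._validate_xy(X, y)
        lo, hi = self.d_bounds

        d_grid = np.geomspace(lo, hi, self.grid_points)
        self._grid_curves_ = {d: self._model(tm, d) for d in d_grid}
        best = None
        for d, m in self._grid_curves_.items():
            a = self._best_amplitude(y, m)
            sse = float(((a * m - y) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, d, a)
        _, d0, a0 = best

        d_hat, a_hat, sol = self._solve(tm, y, d0, a0)
        resid = a_hat * self._model(tm, d_hat) - y
        rms = float(np.sqrt(np.mean(resid**2)))

        converged = bool(sol.success)
        diagnostics = []
        if not sol.success:
            diagnostics.append(f"optimizer: {sol.message}")
        # pinned at the search bounds: the data carry no decay (or too much)
        if d_hat <= lo * 1.5:
            converged = False
            diagnostics.append(
                "D estimate pinned at the lower search bound; the decay is "
                "too shallow to constrain D_lat"
            )
        elif d_hat >= hi / 1.5:
            converged = False
            diagnostics.append("D estimate pinned at the upper search bound")

        self.mixing_times_ = tm
        self.d_lat_ = float(d_hat)
        self.amplitude_ = a_hat
        self.residual_rms_ = rms
        self.converged_ = converged
        self.diagnostics_ = "; ".join(diagnostics)
        self.ci95_ = (math.nan, math.nan)
        self.result_ = DlatFitResult(
            d_lat=self.d_lat_,
            amplitude=self.amplitude_,
            residual_rms=rms,
            converged=converged,
            diagnostics=self.diagnostics_,
            residuals=resid,
        )
        if self.n_boot:
            self.bootstrap_ci(tm, y, n_boot=self.n_boot, seed=self.seed)
        return self

    def predict(self, X):
        """Model curve A * E_pop(t_m; D̂) at the given mixing times."""
        check_is_fitted(self, "d_lat_")
        tm = np.asarray(X, dtype=float)
        if tm.ndim == 2:
            tm = tm[:, 0]
        return self.amplitude_ * self._model(tm, self.d_lat_)

    def bootstrap_ci(
        self, X, y, n_boot: int = 200, seed: int | None = None
    ) -> tuple[float, float]:
        """Residual-resampling bootstrap 95% CI for D_lat.

        Residuals of the fit are leverage-rescaled (r_i / sqrt(1 - h_ii),
        with leverages from the model Jacobian at the point estimate) to
        undo the variance absorbed by the fit, resampled with
        replacement, and added back onto the fitted curve; each synthetic
        dataset is refit (warm-started at the point estimate).  The CI is
        the expanded 2.5/97.5 percentile interval of the refit D values:
        percentile deviations from the point estimate are inflated by
        sqrt(n/(n-1)) * t_{0.975, n-p} / z_{0.975}, the standard
        small-sample correction for percentile intervals, which matters
        for the short (~8-point) decay series typical of these
        experiments.  Deterministic under a fixed seed.
        """
        check_is_fitted(self, "d_lat_")
        if not self.converged_:
            raise ValueError("cannot bootstrap a non-converged fit")
        if n_boot < 50:
            warnings.warn("n_boot < 50 gives unstable percentile CIs", stacklevel=2)
        tm, y = self._validate_xy(X, y)
        rng = np.random.default_rng(seed)
        fitted = self.amplitude_ * self._model(tm, self.d_lat_)
        resid = y - fitted
        n = tm.size
        scaled = resid / np.sqrt(np.clip(1.0 - self._leverages(tm), 0.05, 1.0))

        d_samples = np.empty(n_boot)
        for b in range(n_boot):
            y_star = fitted + rng.choice(scaled, size=n, replace=True)
            d_b, _, _ = self._solve(tm, y_star, self.d_lat_, self.amplitude_)
            d_samples[b] = d_b
        lo_q, hi_q = np.percentile(d_samples, [2.5, 97.5])
        expand = math.sqrt(n / (n - 1)) * (
            student_t.ppf(0.975, max(n - 2, 1)) / norm.ppf(0.975)
        )
        lo_e = self.d_lat_ + expand * (float(lo_q) - self.d_lat_)
        hi_e = self.d_lat_ + expand * (float(hi_q) - self.d_lat_)
        ci = (max(min(lo_e, self.d_lat_), 0.0), max(hi_e, self.d_lat_))
        self.ci95_ = ci
        self.bootstrap_samples_ = d_samples
        self.result_.ci95_low, self.result_.ci95_high = ci
        return ci


def fit_dlat(
    data: CodexDecayDataset,
    dist: VesicleSizeDistribution,
    csa: CSATensor,
    cond: ExperimentConditions,
    config: SingleVesicleModelConfig | None = None,
    tau_echo: float | None = None,
    **kwargs,
) -> DlatFitResult:
    """Fit D_lat for one resonance; see :class:`CodexDiffusionFitter`."""
    est = CodexDiffusionFitter(
        distribution=dist, csa=csa, conditions=cond,
        model_config=config, tau_echo=tau_echo, **kwargs,
    )
    est.fit(data.mixing_times, data.intensities)
    return est.result_


def ci95_bootstrap(
    data: CodexDecayDataset,
    fit: DlatFitResult,
    dist: VesicleSizeDistribution,
    csa: CSATensor,
    cond: ExperimentConditions,
    config: SingleVesicleModelConfig | None = None,
    tau_echo: float | None = None,
    n_boot: int = 200,
    seed: int | None = None,
) -> tuple[float, float]:
    """Residual-bootstrap 95% CI around an existing :func:`fit_dlat` result."""
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    est = CodexDiffusionFitter(
        distribution=dist, csa=csa, conditions=cond,
        model_config=config, tau_echo=tau_echo,
    )
    est.fit(data.mixing_times, data.intensities)
    ci = est.bootstrap_ci(data.mixing_times, data.intensities, n_boot=n_boot, seed=seed)
    fit.ci95_low, fit.ci95_high = ci
    return ci


class InversionRecoveryFitter(RegressorMixin, BaseEstimator):
    """Mono-exponential inversion-recovery fit M(t) = M0 (1 - 2a e^{-t/T1}).

    ``a`` is the inversion factor (1 for perfect inversion).  Fitted
    attributes: ``t1_``, ``m0_``, ``inversion_factor_``, ``converged_``.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 4:
            raise ValueError("inversion recovery needs at least 4 delays")
        m0_guess = float(np.max(np.abs(m)))
        a_guess = float(np.clip((m0_guess - m[0]) / (2 * m0_guess), 0.2, 1.0))
        # zero crossing at t = T1 ln(2a)
        sign_change = np.nonzero(np.diff(np.sign(m)) > 0)[0]
        t1_guess = (
            t[sign_change[0]] / math.log(2 * a_guess)
            if sign_change.size and a_guess > 0.55
            else max(t[-1] / 3.0, t[1])
        )

        def residual(x):
            m0, a, t1 = x
            return m0 * (1.0 - 2.0 * a * np.exp(-t / t1)) - m

        sol = least_squares(
            residual,
            x0=[m0_guess, a_guess, t1_guess],
            bounds=([0.0, 0.0, 1e-12], [np.inf, 1.5, np.inf]),
        )
        self.m0_, self.inversion_factor_, self.t1_ = map(float, sol.x)
        self.converged_ = bool(sol.success and self.t1_ > 0)
        self.result_ = RelaxationFitResult(
            time_constant=self.t1_,
            m0=self.m0_,
            inversion_factor=self.inversion_factor_,
            converged=self.converged_,
            diagnostics="" if sol.success else sol.message,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "t1_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.m0_ * (1.0 - 2.0 * self.inversion_factor_ * np.exp(-t / self.t1_))


class EchoDecayFitter(RegressorMixin, BaseEstimator):
    """Mono-exponential echo decay fit M(tau) = M0 exp(-tau/T2).

    Initialized from the log-linear regression of the positive
    intensities; fitted attributes ``t2_``, ``m0_``, ``converged_``.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 2:
            raise ValueError("echo decay needs at least 2 delays")
        pos = m > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(m[pos]), 1)
            t2_guess = -1.0 / slope if slope < 0 else t[-1]
            m0_guess = math.exp(intercept)
        else:
            t2_guess, m0_guess = t[-1], float(np.max(np.abs(m)))

        def residual(x):
            m0, t2 = x
            return m0 * np.exp(-t / t2) - m

        sol = least_squares(
            residual, x0=[m0_guess, max(t2_guess, 1e-12)],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
        )
        self.m0_, self.t2_ = map(float, sol.x)
        self.converged_ = bool(sol.success)
        self.result_ = RelaxationFitResult(
            time_constant=self.t2_,
            m0=self.m0_,
            converged=self.converged_,
            diagnostics="" if sol.success else sol.message,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "t2_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.m0_ * np.exp(-t / self.t2_)


def fit_t1_inversion_recovery(data: RelaxationDataset) -> RelaxationFitResult:
    """Fit T1 from an inversion-recovery series."""
    if data.mode != "inversion_recovery":
        raise ValueError("dataset mode must be 'inversion_recovery'")
    return InversionRecoveryFitter().fit(data.delays, data.intensities).result_


def fit_t2_echo(data: RelaxationDataset) -> RelaxationFitResult:
    """Fit T2 from a Hahn-echo decay series."""
    if data.mode != "echo_decay":
        raise ValueError("dataset mode must be 'echo_decay'")
    return EchoDecayFitter().fit(data.delays, data.intensities).result_
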