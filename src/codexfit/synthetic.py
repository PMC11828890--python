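"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and seed, so tests
and worked examples run without instrument data: a lognormal-like
number-weighted vesicle radius distribution standing in for a DLS
regularization export, CODEX decays generated by the forward model plus
i.i.d. Gaussian noise, logistic melt curves, and mono-exponential
relaxation series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import lognorm

from .core import CSATensor, ExperimentConditions
from .ensemble import VesicleSizeDistribution, ensemble_codex_decay
from .fitting import CodexDecayDataset, RelaxationDataset
from .spin import SingleVesicleModelConfig
from .transition import MeltCurve

__all__ = [
    "NoiseSpec",
    "lognormal_radius_distribution",
    "synth_codex_dataset",
    "synth_melt_curve",
    "synth_relaxation",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation and RNG seed."""

    sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def lognormal_radius_distribution(
    median: float = 150e-9,
    geometric_sd: float = 1.5,
    n_points: int = 60,
    r_min: float = 20e-9,
    r_max: float = 1000e-9,
) -> VesicleSizeDistribution:
    """Discretized lognormal number-weighted radius distribution.

    Bin masses are cumulative-distribution differences over a geometric
    grid, so the discrete median tracks the requested one to within a
    bin.  The defaults (median 150 nm, geometric SD 1.5, 60 points over
    20-1000 nm) emulate the shape of a number-weighted DLS distribution
    of extruded-liposome suspensions.
    """
    if geometric_sd < 1:
        raise ValueError("geometric_sd must be >= 1")
    if not r_min < median < r_max:
        raise ValueError("require r_min < median < r_max")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    edges = np.geomspace(r_min, r_max, n_points + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    if geometric_sd == 1.0:
        p = np.zeros(n_points)
        p[np.searchsorted(edges, median) - 1] = 1.0
    else:
        s = math.log(geometric_sd)
        cdf = lognorm.cdf(edges, s=s, scale=median)
        p = np.diff(cdf)
        p[0] += cdf[0]
        p[-1] += 1.0 - cdf[-1]
    return VesicleSizeDistribution(radii=centers, probability=p / p.sum())


def synth_codex_dataset(
    d_true: float,
    dist: VesicleSizeDistribution,
    csa: CSATensor,
    cond: ExperimentConditions,
    mixing_times,
    noise: NoiseSpec = NoiseSpec(),
    config: SingleVesicleModelConfig | None = None,
    tau_echo: float | None = None,
    amplitude: float = 1.0,
) -> CodexDecayDataset:
    """Forward-model CODEX decay at a known D_lat plus Gaussian noise."""
    curve = ensemble_codex_decay(
        dist, d_true, csa, cond, mixing_times, config=config, tau_echo=tau_echo
    )
    signal = amplitude * curve.signal
    if noise.sd > 0:
        signal = signal + noise.rng().normal(scale=noise.sd, size=signal.shape)
    return CodexDecayDataset(
        label=csa.label,
        mixing_times=curve.mixing_times,
        intensities=signal,
        uncertainties=np.full_like(signal, noise.sd) if noise.sd > 0 else None,
    )


def synth_melt_curve(
    tm: float,
    width: float,
    t_range: tuple[float, float],
    n_points: int = 24,
    noise: NoiseSpec = NoiseSpec(),
) -> MeltCurve:
    """Logistic melt curve centred at ``tm`` plus Gaussian noise.

    ``width`` is the 10-90% rise span in °C (logistic scale
    width / (2 ln 9)); intensities rise from 0 to 1 across the
    transition.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if n_points < 6:
        raise ValueError("need at least 6 points")
    lo, hi = t_range
    if not lo < tm < hi:
        raise ValueError("tm must lie inside t_range")
    t = np.linspace(lo, hi, n_points)
    scale = width / (2.0 * math.log(9.0))
    i = 1.0 / (1.0 + np.exp(-(t - tm) / scale))
    if noise.sd > 0:
        i = i + noise.rng().normal(scale=noise.sd, size=i.shape)
    return MeltCurve(temperatures=t, intensities=i)


def synth_relaxation(
    mode: str,
    time_constant: float,
    delays,
    noise: NoiseSpec = NoiseSpec(),
    m0: float = 1.0,
    inversion_factor: float = 1.0,
) -> RelaxationDataset:
    """Mono-exponential relaxation series for either fit mode.

    ``inversion_recovery``: M(t) = M0 (1 - 2a exp(-t/T1));
    ``echo_decay``:         M(t) = M0 exp(-t/T2).
    """
    if time_constant <= 0:
        raise ValueError("time constant must be positive")
    delays = np.asarray(delays, dtype=float)
    if mode == "inversion_recovery":
        m = m0 * (1.0 - 2.0 * inversion_factor * np.exp(-delays / time_constant))
    elif mode == "echo_decay":
        m = m0 * np.exp(-delays / time_constant)
    else:
        raise ValueError("mode must be 'inversion_recovery' or 'echo_decay'")
    if noise.sd > 0:
        m = m + noise.rng().normal(scale=noise.sd, size=m.shape)
    return RelaxationDataset(delays=delays, intensities=m, mode=mode)
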