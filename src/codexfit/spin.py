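"""Forward model for the CODEX signal of a single spherical vesicle.

The CODEX experiment encodes the orientation of each lipid's motionally
averaged ³¹P shift tensor (unique axis along the local membrane normal)
through a recoupled-CSA phase accumulated under MAS, stores it across a
mixing period during which the normal reorients — by lateral diffusion of
the lipid over the vesicle surface and by tumbling of the whole vesicle —
and then attempts to refocus it.  The surviving signal is

    E(t_m) = < cos( Phi(n0) - Phi(n_tm) ) >

with ``n0`` powder-averaged over the sphere and ``n_tm`` distributed
according to the diffusion Green's function on the sphere.

The Green's function is diagonal in Legendre order, so the mixing-time
dependence factorizes: expanding the orientational phase correlation
C(u) = <cos(Phi(n0) - Phi(n_u))> (u = cosine of the displacement angle,
averaged over the azimuth of the displacement ring and the starting
powder) in Legendre polynomials with Gauss-Legendre quadrature gives
coefficients ``a_l`` that depend only on the tensor, the spinning
conditions and the quadrature — not on the vesicle radius, diffusion
coefficient or mixing time.  The decay is then

    E(t_m) = sum_l  a_l  exp( -l(l+1) d_ang t_m )

with the combined angular diffusion coefficient
``d_ang = D_lat/r^2 + kB T / (8 pi eta r^3)``.  The coefficients are
cached per (tensor, conditions, quadrature), which makes ensemble sums,
least-squares fits and bootstraps cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import eval_legendre

from .core import (
    BOLTZMANN,
    MAGIC_ANGLE,
    CSATensor,
    ExperimentConditions,
    ppm_to_angular_frequency,
)

__all__ = [
    "OrientationGrid",
    "SingleVesicleModelConfig",
    "CodexCurve",
    "recoupled_phase",
    "sphere_propagator_moment",
    "angular_diffusion_coefficient",
    "orientation_correlation_coefficients",
    "single_vesicle_codex_decay",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class OrientationGrid:
    """Discrete powder average over the unit sphere.

    Attributes
    ----------
    beta, gamma : ndarray
        Polar and azimuthal angles of each orientation, rad.
    weights : ndarray
        Non-negative quadrature weights summing to 1.
    """

    beta: np.ndarray
    gamma: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("quadrature weights must be non-negative")
        total = self.weights.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("quadrature weights must sum to 1")

    def __len__(self) -> int:
        return self.beta.size

    @classmethod
    def fibonacci(cls, n: int) -> "OrientationGrid":
        """Equal-area spiral (Fibonacci) grid with uniform weights.

        Low-discrepancy coverage of the sphere; the second moment
        ``sum_i w_i P2(cos beta_i)`` vanishes to O(1/n).
        """
        if n < 2:
            raise ValueError("grid needs at least 2 orientations")
        i = np.arange(n)
        z = (2.0 * i + 1.0) / n - 1.0
        beta = np.arccos(np.clip(z, -1.0, 1.0))
        gamma = np.mod(i * _GOLDEN_ANGLE, 2.0 * math.pi)
        w = np.full(n, 1.0 / n)
        return cls(beta=beta, gamma=gamma, weights=w)

    def unit_vectors(self) -> np.ndarray:
        """(n, 3) Cartesian unit vectors of the grid points."""
        sb = np.sin(self.beta)
        return np.stack(
            [sb * np.cos(self.gamma), sb * np.sin(self.gamma), np.cos(self.beta)],
            axis=1,
        )


@dataclass(frozen=True)
class SingleVesicleModelConfig:
    """Numerical resolution of the single-vesicle decay model.

    Parameters
    ----------
    grid_size : int
        Number of powder orientations (equal-area spiral).
    legendre_truncation : int
        Highest Legendre order L kept in the sphere-diffusion expansion.
    integration_steps_per_rotor_period : int
        Trapezoidal time steps per rotor period when integrating the MAS
        frequency across the recoupling train.
    displacement_quadrature_size : int
        Gauss-Legendre nodes over the cosine of the displacement angle;
        also used as the azimuth count of the displacement ring.  Should
        exceed ``legendre_truncation`` for exact Legendre projection.
    tolerance : float
        Acceptable truncation tail |1 - sum_l a_l|; exceeded -> a
        convergence warning is carried in the result metadata.
    include_tumbling : bool
        If False, the whole-vesicle tumbling term is dropped from the
        mixing-time propagator and only lateral diffusion reorients the
        tensor (comparison switch; tumbling still enters the echo
        survival weight of the ensemble model).
    """

    grid_size: int = 2000
    legendre_truncation: int = 40
    integration_steps_per_rotor_period: int = 64
    displacement_quadrature_size: int = 48
    tolerance: float = 1e-3
    include_tumbling: bool = True

    def __post_init__(self) -> None:
        for name in (
            "grid_size",
            "legendre_truncation",
            "integration_steps_per_rotor_period",
            "displacement_quadrature_size",
        ):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CodexCurve:
    """A normalized CODEX decay: E(t_m) versus mixing time."""

    mixing_times: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mixing_times.shape != self.signal.shape:
            raise ValueError("mixing_times and signal must have equal length")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal values must be finite")


def _validate_mixing_times(mixing_times: np.ndarray, cond: ExperimentConditions) -> None:
    if np.any(mixing_times < 0):
        raise ValueError("mixing times must be non-negative")
    if np.any(np.diff(mixing_times) <= 0):
        raise ValueError("mixing times must be strictly increasing")
    tr = cond.rotor_period
    frac = np.abs(mixing_times / tr - np.round(mixing_times / tr))
    if np.any(frac > 1e-3):
        warnings.warn(
            "mixing times are not integer multiples of the rotor period; "
            "the model assumes rotor-synchronized mixing",
            stacklevel=3,
        )


def _axial_mas_frequency(
    t: np.ndarray, beta: np.ndarray, gamma: np.ndarray, csa: CSATensor, cond: ExperimentConditions
) -> np.ndarray:
    """Anisotropic MAS frequency (rad/s) of an axial tensor.

    ``t`` has shape (T,), ``beta``/``gamma`` shape (M,); returns (M, T).
    The tensor's unique axis sits at (beta, gamma) in the rotor-fixed
    frame; the B0 direction precesses about the rotor axis at the magic
    angle.  The isotropic shift is excluded: it is identical in the
    dephasing and rephasing periods and cancels in the phase difference.
    """
    w_aniso = ppm_to_angular_frequency(csa.delta_cs, cond.larmor_frequency)
    wr = 2.0 * math.pi * cond.mas_rate
    cm, sm = math.cos(MAGIC_ANGLE), math.sin(MAGIC_ANGLE)
    cb, sb = np.cos(beta)[:, None], np.sin(beta)[:, None]
    cos_theta = cm * cb + sm * sb * np.cos(wr * t[None, :] + gamma[:, None])
    return w_aniso * 0.5 * (3.0 * cos_theta**2 - 1.0)


def _general_mas_frequency(
    t: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    csa: CSATensor,
    cond: ExperimentConditions,
) -> np.ndarray:
    """Anisotropic MAS frequency for an arbitrary (eta != 0) tensor.

    The traceless shift tensor is rotated from its principal axis system
    into the rotor frame by ZYZ Euler angles (alpha, beta, gamma) and
    projected onto the precessing B0 direction.
    """
    scale = ppm_to_angular_frequency(1.0, cond.larmor_frequency)
    d = csa.delta_cs
    eta = csa.eta_csa
    # Haeberlen principal deviations (traceless part).
    pas = np.diag([-d * (1.0 + eta) / 2.0, -d * (1.0 - eta) / 2.0, d])

    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    # R = Rz(gamma) Ry(beta) Rz(alpha), shape (M, 3, 3)
    r = np.empty((alpha.size, 3, 3))
    r[:, 0, 0] = cg * cb * ca - sg * sa
    r[:, 0, 1] = -cg * cb * sa - sg * ca
    r[:, 0, 2] = cg * sb
    r[:, 1, 0] = sg * cb * ca + cg * sa
    r[:, 1, 1] = -sg * cb * sa + cg * ca
    r[:, 1, 2] = sg * sb
    r[:, 2, 0] = -sb * ca
    r[:, 2, 1] = sb * sa
    r[:, 2, 2] = cb
    a_rot = np.einsum("mij,jk,mlk->mil", r, pas, r)

    wr = 2.0 * math.pi * cond.mas_rate
    cm, sm = math.cos(MAGIC_ANGLE), math.sin(MAGIC_ANGLE)
    b = np.stack(
        [sm * np.cos(wr * t), sm * np.sin(wr * t), np.full_like(t, cm)], axis=1
    )  # (T, 3)
    return scale * np.einsum("ti,mij,tj->mt", b, a_rot, b)


def _recoupled_phases(
    beta: np.ndarray,
    gamma: np.ndarray,
    csa: CSATensor,
    cond: ExperimentConditions,
    steps_per_rotor: int,
    alpha: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized toggled phase over one recoupling period, shape (M,).

    The period lasts N*t_r/2 with pi pulses every half rotor period; the
    integrand's sign alternates between pulses.  Each half-rotor segment
    is integrated with the trapezoidal rule.
    """
    tr = cond.rotor_period
    n = cond.n_pi_pulses
    m = max(2, steps_per_rotor // 2)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    total = np.zeros(np.broadcast(beta, gamma).shape, dtype=float)
    for k in range(n):
        t = np.linspace(k * tr / 2.0, (k + 1) * tr / 2.0, m + 1)
        if csa.eta_csa == 0.0:
            w = _axial_mas_frequency(t, beta, gamma, csa, cond)
        else:
            a = np.zeros_like(beta) if alpha is None else np.atleast_1d(alpha)
            w = _general_mas_frequency(t, a, beta, gamma, csa, cond)
        total += (-1) ** k * np.trapezoid(w, t, axis=1)
    return total


def recoupled_phase(
    beta: float,
    gamma: float,
    csa: CSATensor,
    cond: ExperimentConditions,
    steps_per_rotor: int = 64,
    alpha: float = 0.0,
) -> float:
    """Net CSA phase accumulated over one CODEX recoupling period, rad.

    The rotor-synchronized pi-pulse train (``cond.n_pi_pulses`` pulses
    spaced t_r/2 apart) toggles the sign of the MAS time-dependent CSA
    frequency so the anisotropic interaction no longer averages to zero
    over the rotor cycle; a tensor whose unique axis sits at ``(beta,
    gamma)`` in the rotor frame acquires an orientation-dependent phase.
    The isotropic shift drops out of the phase difference between the two
    recoupling periods and is excluded here.

    For an orientation along the rotor axis (``beta = 0``) the MAS
    modulation vanishes — at the magic angle the static second-rank term
    is zero — and the phase is exactly 0.
    """
    if not (math.isfinite(beta) and math.isfinite(gamma)):
        raise ValueError("orientation angles must be finite")
    return float(
        _recoupled_phases(
            np.array([beta]), np.array([gamma]), csa, cond, steps_per_rotor,
            alpha=np.array([alpha]),
        )[0]
    )


def sphere_propagator_moment(l: int, t: float, d_ang: float) -> float:
    """Legendre-moment decay of the diffusion Green's function on a sphere.

    The Green's function of isotropic diffusion on the unit sphere with
    angular diffusion coefficient ``d_ang`` decays mode-by-mode as
    ``exp(-l(l+1) d_ang t)``.
    """
    if l < 0:
        raise ValueError("harmonic order must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    if d_ang < 0:
        raise ValueError("angular diffusion coefficient must be non-negative")
    return math.exp(-l * (l + 1) * d_ang * t)


def angular_diffusion_coefficient(
    r: float,
    d_lat: float,
    cond: ExperimentConditions,
    include_tumbling: bool = True,
) -> float:
    """Combined angular diffusion coefficient of the membrane normal, 1/s.

    Lateral diffusion of a lipid over a vesicle of radius ``r`` moves its
    local normal with angular coefficient ``D_lat / r^2``; rigid-body
    tumbling of the vesicle adds the Stokes-Einstein-Debye rate
    ``kB T / (8 pi eta r^3)``.  Six times the combined coefficient equals
    the inverse rotational correlation time ``1/tau_c``.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if d_lat < 0:
        raise ValueError("lateral diffusion coefficient must be non-negative")
    d = d_lat / r**2
    if include_tumbling:
        d += BOLTZMANN * cond.temperature / (8.0 * math.pi * cond.viscosity * r**3)
    return d


@lru_cache(maxsize=32)
def _cached_correlation(
    csa: CSATensor, cond: ExperimentConditions, config: SingleVesicleModelConfig
) -> tuple[tuple[float, ...], float]:
    a_l, tail = _compute_correlation(csa, cond, config)
    return tuple(a_l), tail


def _compute_correlation(
    csa: CSATensor, cond: ExperimentConditions, config: SingleVesicleModelConfig
) -> tuple[np.ndarray, float]:
    """Legendre coefficients a_l of the orientational phase correlation.

    Builds C(u_j) = <cos(Phi(n0) - Phi(n_j))> on Gauss-Legendre nodes u_j
    (cosine of the displacement angle, azimuth-ring and powder averaged)
    and projects onto Legendre polynomials.  a_0 is the infinite-time
    plateau |<exp(i Phi)>|^2; sum_l a_l approximates C(1) = 1 and the
    deficit is the reported truncation tail.
    """
    if csa.eta_csa > 1e-6:
        raise NotImplementedError(
            "the vesicle decay model requires an axially symmetric tensor "
            "(eta_csa = 0); non-axial tensors are supported only by the "
            "sideband simulator"
        )
    grid = OrientationGrid.fibonacci(config.grid_size)
    n0 = grid.unit_vectors()  # (M, 3)
    w0 = grid.weights
    steps = config.integration_steps_per_rotor_period
    phi0 = _recoupled_phases(grid.beta, grid.gamma, csa, cond, steps)

    # Orthonormal tangent frame at each n0.
    ref = np.where(np.abs(n0[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, n0)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n0, e1)

    n_u = config.displacement_quadrature_size
    u, wu = np.polynomial.legendre.leggauss(n_u)
    n_phi = config.displacement_quadrature_size
    phi_ring = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
    cos_p, sin_p = np.cos(phi_ring), np.sin(phi_ring)

    c_u = np.empty(n_u)
    for j, uj in enumerate(u):
        s = math.sqrt(max(0.0, 1.0 - uj * uj))
        # displaced normals, shape (M, n_phi, 3)
        nt = (
            uj * n0[:, None, :]
            + s * (cos_p[None, :, None] * e1[:, None, :] + sin_p[None, :, None] * e2[:, None, :])
        )
        beta_t = np.arccos(np.clip(nt[..., 2], -1.0, 1.0)).ravel()
        gamma_t = np.arctan2(nt[..., 1], nt[..., 0]).ravel()
        phi_t = _recoupled_phases(beta_t, gamma_t, csa, cond, steps)
        phi_t = phi_t.reshape(len(grid), n_phi)
        c_u[j] = float(np.sum(w0 * np.mean(np.cos(phi0[:, None] - phi_t), axis=1)))

    lmax = config.legendre_truncation
    orders = np.arange(lmax + 1)
    p_lu = eval_legendre(orders[:, None], u[None, :])  # (L+1, n_u)
    a_l = (orders + 0.5) * (p_lu * (wu * c_u)[None, :]).sum(axis=1)
    tail = 1.0 - float(a_l.sum())
    return a_l, tail


def orientation_correlation_coefficients(
    csa: CSATensor, cond: ExperimentConditions, config: SingleVesicleModelConfig
) -> tuple[np.ndarray, float]:
    """Cached Legendre spectrum of the recoupled-phase correlation.

    Returns ``(a_l, tail)`` where ``E(t) = sum_l a_l exp(-l(l+1) d_ang t)``
    and ``tail = 1 - sum_l a_l`` measures the Legendre truncation error.
    """
    a_l, tail = _cached_correlation(csa, cond, config)
    return np.array(a_l), tail


def single_vesicle_codex_decay(
    r: float,
    d_lat: float,
    csa: CSATensor,
    cond: ExperimentConditions,
    mixing_times,
    config: SingleVesicleModelConfig | None = None,
) -> CodexCurve:
    """Pure-exchange CODEX decay E(t_m) for one vesicle radius.

    The curve is reference-compensated (an S/S0 pair): relaxation during
    the mixing period is assumed divided out, so E(0) = 1 exactly and the
    long-time plateau is the powder average |<exp(i Phi)>|^2.

    Parameters
    ----------
    r : float
        Vesicle radius, m.
    d_lat : float
        Lateral diffusion coefficient, m²/s.
    mixing_times : array-like
        Non-negative, strictly increasing mixing times, s; integer
        multiples of the rotor period (a deviation only warns).
    """
    if config is None:
        config = SingleVesicleModelConfig()
    mixing_times = np.asarray(mixing_times, dtype=float)
    _validate_mixing_times(mixing_times, cond)

    a_l, tail = orientation_correlation_coefficients(csa, cond, config)
    d_ang = angular_diffusion_coefficient(
        r, d_lat, cond, include_tumbling=config.include_tumbling
    )
    orders = np.arange(a_l.size)
    rates = orders * (orders + 1) * d_ang
    e = (a_l[None, :] * np.exp(-np.outer(mixing_times, rates))).sum(axis=1)
    e[mixing_times == 0.0] = 1.0
    if d_ang == 0.0:
        e[:] = 1.0

    meta = {"truncation_tail": tail, "converged": abs(tail) <= config.tolerance}
    if not meta["converged"]:
        meta["warnings"] = [
            f"Legendre truncation tail {tail:.2e} exceeds tolerance "
            f"{config.tolerance:.2e}; increase legendre_truncation"
        ]
    return CodexCurve(mixing_times=mixing_times, signal=e, meta=meta)
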