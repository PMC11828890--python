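"""Independent brute-force oracles for cross-checking the forward model.

Everything here deliberately avoids the library's quadrature machinery:
phases are midpoint-Riemann integrals of the toggled MAS frequency
written from scratch, sphere diffusion is an explicit random walk of
tangent-plane Gaussian steps, and vesicle radii are sampled directly
from independently recomputed signal weights.
"""

import math

import numpy as np

BOLTZMANN = 1.380649e-23
MAGIC = math.acos(1.0 / math.sqrt(3.0))


def riemann_phase(vectors, csa, cond, nsteps=1536):
    """Toggled recoupling phase of axial tensors at unit-vector orientations.

    Midpoint Riemann sum over the N*t_r/2 recoupling period with the sign
    flipped every half rotor period.
    """
    tr = 1.0 / cond.mas_rate
    duration = cond.n_pi_pulses * tr / 2.0
    t = (np.arange(nsteps) + 0.5) * (duration / nsteps)
    sign = np.where(np.floor(2.0 * t / tr).astype(int) % 2 == 0, 1.0, -1.0)
    wr = 2.0 * math.pi * cond.mas_rate
    w_aniso = 2.0 * math.pi * csa.delta_cs * cond.larmor_frequency
    beta = np.arccos(np.clip(vectors[:, 2], -1.0, 1.0))
    gamma = np.arctan2(vectors[:, 1], vectors[:, 0])
    cos_theta = (
        math.cos(MAGIC) * np.cos(beta)[:, None]
        + math.sin(MAGIC) * np.sin(beta)[:, None] * np.cos(wr * t[None, :] + gamma[:, None])
    )
    freq = w_aniso * 0.5 * (3.0 * cos_theta**2 - 1.0)
    return (freq * sign[None, :]).sum(axis=1) * (duration / nsteps)


def _tangent_step(v, rng, scale):
    """One random-walk step: tangent-plane Gaussian, exact-rotation update."""
    ref = np.where(np.abs(v[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, v)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(v, e1)
    g = rng.normal(scale=scale, size=(v.shape[0], 2))
    angle = np.hypot(g[:, 0], g[:, 1])
    with np.errstate(invalid="ignore"):
        direction = (g[:, 0:1] * e1 + g[:, 1:2] * e2) / angle[:, None]
    direction = np.where(angle[:, None] > 0, direction, 0.0)
    v_new = v * np.cos(angle)[:, None] + direction * np.sin(angle)[:, None]
    return v_new / np.linalg.norm(v_new, axis=1, keepdims=True)


def mc_codex_decay(d_ang, csa, cond, mixing_times, n_walkers=30000, seed=0,
                   steps_per_interval=60):
    """CODEX decay by random walk on the sphere at a given angular coefficient.

    ``d_ang`` may be a scalar or a per-walker array (for ensemble sampling).
    """
    rng = np.random.default_rng(seed)
    d_ang = np.broadcast_to(np.asarray(d_ang, dtype=float), (n_walkers,))
    v = rng.normal(size=(n_walkers, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    phi0 = riemann_phase(v, csa, cond)
    decay = []
    t_prev = 0.0
    for tm in mixing_times:
        dt = (tm - t_prev) / steps_per_interval
        t_prev = tm
        scale = np.sqrt(2.0 * d_ang * dt)[:, None] * np.ones((1, 2))
        for _ in range(steps_per_interval):
            v = _tangent_step(v, rng, scale[:, 0:2])
        decay.append(float(np.mean(np.cos(phi0 - riemann_phase(v, csa, cond)))))
    return np.array(decay)


def mc_single_vesicle_decay(r, d_lat, csa, cond, mixing_times, n_walkers=30000,
                            seed=0):
    """Single-vesicle oracle: tumbling + lateral diffusion combined."""
    d_ang = d_lat / r**2 + BOLTZMANN * cond.temperature / (
        8.0 * math.pi * cond.viscosity * r**3
    )
    return mc_codex_decay(d_ang, csa, cond, mixing_times, n_walkers, seed)


def mc_ensemble_decay(dist, d_lat, csa, cond, mixing_times, tau_echo,
                      n_walkers=30000, seed=0):
    """Population oracle: radii sampled from independently computed weights."""
    r = dist.radii
    tumble = BOLTZMANN * cond.temperature / (8.0 * math.pi * cond.viscosity * r**3)
    d_ang_r = d_lat / r**2 + tumble
    tau_c = 1.0 / (6.0 * d_ang_r)
    w = dist.probability * 8.0 * math.pi * r**2 * np.exp(-tau_echo / tau_c)
    w = w / w.sum()
    rng = np.random.default_rng(seed + 1)
    picks = rng.choice(r.size, size=n_walkers, p=w)
    return mc_codex_decay(d_ang_r[picks], csa, cond, mixing_times, n_walkers, seed)
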