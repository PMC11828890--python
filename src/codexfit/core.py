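"""Shared domain types, physical constants and unit conversions.

Internally every quantity is SI (s, m, K, Pa·s, rad/s).  The two
spectroscopy-facing units that survive at the boundaries are ppm (chemical
shift scale) and MPa (pressure annotation); helpers here bridge them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "BOLTZMANN",
    "STANDARD_GRAVITY",
    "MAGIC_ANGLE",
    "CSATensor",
    "ExperimentConditions",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "ppm_to_angular_frequency",
    "rotor_period",
    "load_conditions",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Standard acceleration of gravity used for relative-centrifugal-force
#: reporting, m/s^2.
STANDARD_GRAVITY = 9.81

#: Magic angle: arccos(1/sqrt(3)), the rotor-axis tilt from B0 under MAS, rad.
MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from Celsius to Kelvin."""
    return t_celsius + 273.15


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature from Kelvin to Celsius."""
    return t_kelvin - 273.15


@dataclass(frozen=True)
class CSATensor:
    """Motionally averaged ³¹P chemical-shift tensor of a phospholipid.

    For fluid-phase lipids, fast axial rotation about the bilayer normal
    averages the static shift tensor to (near) axial symmetry with unique
    axis along the membrane normal.  The residual anisotropy is reported
    in the Haeberlen-style convention

    ``delta_cs = delta_parallel - delta_iso``  (ppm, signed)

    and is stored exactly as measured, without re-deriving principal
    values.  ``eta_csa`` defaults to 0 (axially symmetric); a nonzero
    value is honoured by the sideband simulator.

    Parameters
    ----------
    delta_iso : float
        Isotropic chemical shift, ppm.
    delta_cs : float
        Anisotropy ``delta_parallel - delta_iso``, ppm (signed).
    eta_csa : float, optional
        Asymmetry parameter in [0, 1].  Default 0.
    label : str, optional
        Resonance name, e.g. ``"PE"`` or ``"PG"``.
    """

    delta_iso: float
    delta_cs: float
    eta_csa: float = 0.0
    label: str = "31P"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_cs) or not math.isfinite(self.delta_iso):
            raise ValueError("chemical shift parameters must be finite")
        if not 0.0 <= self.eta_csa <= 1.0:
            raise ValueError(f"eta_csa must lie in [0, 1], got {self.eta_csa}")
        if not self.label:
            raise ValueError("resonance label must be non-empty")


@dataclass(frozen=True)
class ExperimentConditions:
    """Sample and spectrometer conditions for a CODEX measurement.

    Parameters
    ----------
    temperature : float
        Sample temperature, K.
    viscosity : float
        Viscosity of the suspending solution, Pa·s.  Enters the
        Stokes-Einstein-Debye vesicle tumbling rate.
    mas_rate : float
        Magic-angle spinning rate, Hz.
    larmor_frequency : float
        ³¹P Larmor frequency, MHz (sets the Hz-per-ppm scale).
    n_pi_pulses : int, optional
        Number of pi pulses per CSA recoupling period, spaced half a
        rotor period apart.  Default 3.
    pressure : float or None, optional
        Sample pressure, MPa.  Annotation only; the spin model does not
        consume it.
    """

    temperature: float
    viscosity: float
    mas_rate: float
    larmor_frequency: float
    n_pi_pulses: int = 3
    pressure: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.mas_rate <= 0:
            raise ValueError("mas_rate must be positive")
        if self.larmor_frequency <= 0:
            raise ValueError("larmor_frequency must be positive")
        if self.n_pi_pulses < 1:
            raise ValueError("n_pi_pulses must be >= 1")

    @property
    def rotor_period(self) -> float:
        """One rotor period 1/mas_rate, s."""
        return 1.0 / self.mas_rate


def ppm_to_angular_frequency(shift_ppm: float, larmor_mhz: float) -> float:
    """Convert a shift in ppm to an angular frequency in rad/s.

    At a Larmor frequency of ``larmor_mhz`` MHz, 1 ppm corresponds to
    ``larmor_mhz`` Hz, hence ``2*pi*larmor_mhz`` rad/s.

    Parameters
    ----------
    shift_ppm : float
        Chemical shift (or anisotropy), ppm.
    larmor_mhz : float
        Larmor frequency, MHz.  Must be positive.
    """
    if larmor_mhz <= 0:
        raise ValueError("larmor frequency must be positive")
    return 2.0 * math.pi * shift_ppm * larmor_mhz


def rotor_period(mas_rate: float) -> float:
    """Rotor period 1/nu_r in seconds for a MAS rate in Hz."""
    if mas_rate <= 0:
        raise ValueError("MAS rate must be positive")
    return 1.0 / mas_rate


_CONFIG_KEYS = {
    "temperature_C",
    "viscosity_Pa_s",
    "mas_rate_Hz",
    "larmor_MHz",
    "n_pi_pulses",
    "pressure_MPa",
}


def load_conditions(path: str | Path) -> ExperimentConditions:
    """Read experiment conditions from a JSON config file.

    Recognised keys: ``temperature_C``, ``viscosity_Pa_s``, ``mas_rate_Hz``,
    ``larmor_MHz``, ``n_pi_pulses`` (optional), ``pressure_MPa`` (optional).
    Unknown keys are rejected so that typos do not silently fall back to
    defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"allowed: {sorted(_CONFIG_KEYS)}"
        )
    missing = {"temperature_C", "viscosity_Pa_s", "mas_rate_Hz", "larmor_MHz"} - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required config keys {sorted(missing)}")
    return ExperimentConditions(
        temperature=celsius_to_kelvin(float(raw["temperature_C"])),
        viscosity=float(raw["viscosity_Pa_s"]),
        mas_rate=float(raw["mas_rate_Hz"]),
        larmor_frequency=float(raw["larmor_MHz"]),
        n_pi_pulses=int(raw.get("n_pi_pulses", 3)),
        pressure=float(raw["pressure_MPa"]) if "pressure_MPa" in raw else None,
    )
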