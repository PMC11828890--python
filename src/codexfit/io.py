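"""Readers and writers for the delimited-table and JSON report formats.

All tables are comma-separated UTF-8 with a required header row and "."
decimals.  Parse errors name the offending line (1-based, counting the
header as line 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import VesicleSizeDistribution
from .fitting import CodexDecayDataset, DlatFitResult, RelaxationDataset
from .sidebands import SidebandManifold
from .transition import MeltCurve

__all__ = [
    "TableFormatError",
    "read_codex_table",
    "write_codex_table",
    "read_dls_table",
    "write_dls_table",
    "read_melt_table",
    "write_melt_table",
    "read_relaxation_table",
    "read_sideband_table",
    "write_fit_report",
    "file_sha256",
]

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """A delimited input file violates the expected format."""


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.index[values.isna() & df[column].notna()]
    if len(bad):
        raise TableFormatError(
            f"{path}: non-numeric value in column '{column}' at line {bad[0] + 2}"
        )
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2
        raise TableFormatError(f"{path}: empty cell in column '{column}' at line {line}")
    return values.to_numpy(dtype=float)


def read_codex_table(path: str | Path) -> list[CodexDecayDataset]:
    """Read a CODEX decay table, one dataset per resonance.

    Columns: ``resonance``, ``mixing_time_s``, ``intensity`` and optional
    ``sigma``.  Rows are grouped by resonance in order of first
    appearance and sorted by mixing time; duplicate (resonance, time)
    rows and negative times are parse errors naming the line.
    """
    path = Path(path)
    df = _read_table(path, {"resonance", "mixing_time_s", "intensity"})
    times = _numeric(df, "mixing_time_s", path)
    intens = _numeric(df, "intensity", path)
    sigma = _numeric(df, "sigma", path) if "sigma" in df.columns else None

    neg = np.nonzero(times < 0)[0]
    if neg.size:
        raise TableFormatError(
            f"{path}: negative mixing time at line {int(neg[0]) + 2}"
        )
    dup = df.assign(_t=times).duplicated(subset=["resonance", "_t"])
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise TableFormatError(
            f"{path}: duplicate (resonance, mixing_time) row at line {line}"
        )

    datasets = []
    for label in df["resonance"].astype(str).drop_duplicates():
        mask = (df["resonance"].astype(str) == label).to_numpy()
        order = np.argsort(times[mask], kind="stable")
        datasets.append(
            CodexDecayDataset(
                label=label,
                mixing_times=times[mask][order],
                intensities=intens[mask][order],
                uncertainties=sigma[mask][order] if sigma is not None else None,
            )
        )
    return datasets


def write_codex_table(datasets: list[CodexDecayDataset], path: str | Path) -> None:
    """Write CODEX datasets in the format :func:`read_codex_table` reads."""
    frames = []
    for ds in datasets:
        frame = pd.DataFrame(
            {
                "resonance": ds.label,
                "mixing_time_s": ds.mixing_times,
                "intensity": ds.intensities,
            }
        )
        if ds.uncertainties is not None:
            frame["sigma"] = ds.uncertainties
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dls_table(path: str | Path) -> VesicleSizeDistribution:
    """Read a number-weighted DLS size distribution.

    Columns: ``radius_nm``, ``number_fraction``.  Radii are converted to
    metres and sorted; fractions off unity by more than 1e-3 are
    renormalized with a logged warning.
    """
    path = Path(path)
    df = _read_table(path, {"radius_nm", "number_fraction"})
    radii_nm = _numeric(df, "radius_nm", path)
    fractions = _numeric(df, "number_fraction", path)
    nonpos = np.nonzero(radii_nm <= 0)[0]
    if nonpos.size:
        raise TableFormatError(
            f"{path}: non-positive radius at line {int(nonpos[0]) + 2}"
        )
    return VesicleSizeDistribution.from_fractions(radii_nm * 1e-9, fractions)


def write_dls_table(dist: VesicleSizeDistribution, path: str | Path) -> None:
    """Write a size distribution in the format :func:`read_dls_table` reads."""
    pd.DataFrame(
        {"radius_nm": dist.radii * 1e9, "number_fraction": dist.probability}
    ).to_csv(path, index=False)


def read_melt_table(path: str | Path) -> MeltCurve:
    """Read a variable-temperature intensity series.

    Columns: ``temperature_C``, ``intensity``; rows are sorted by
    temperature.
    """
    path = Path(path)
    df = _read_table(path, {"temperature_C", "intensity"})
    t = _numeric(df, "temperature_C", path)
    i = _numeric(df, "intensity", path)
    order = np.argsort(t)
    return MeltCurve(temperatures=t[order], intensities=i[order])


def write_melt_table(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"temperature_C": curve.temperatures, "intensity": curve.intensities}
    ).to_csv(path, index=False)


def read_relaxation_table(path: str | Path, mode: str) -> RelaxationDataset:
    """Read a relaxation series (columns ``delay_s``, ``intensity``)."""
    path = Path(path)
    df = _read_table(path, {"delay_s", "intensity"})
    t = _numeric(df, "delay_s", path)
    i = _numeric(df, "intensity", path)
    order = np.argsort(t)
    return RelaxationDataset(delays=t[order], intensities=i[order], mode=mode)


def read_sideband_table(path: str | Path) -> SidebandManifold:
    """Read a sideband manifold table (columns ``order_k``, ``intensity``)."""
    path = Path(path)
    df = _read_table(path, {"order_k", "intensity"})
    k = _numeric(df, "order_k", path)
    if not np.allclose(k, np.round(k)):
        raise TableFormatError(f"{path}: order_k must be integers")
    return SidebandManifold(
        orders=k.astype(int), intensities=_numeric(df, "intensity", path)
    )


def write_fit_report(
    result: DlatFitResult,
    path: str | Path,
    config_echo: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a D_lat fit result as a JSON report.

    Carries the estimate in both m²/s and the reporting unit 10⁻¹² m²/s,
    the 95% CI, amplitude, residual series, a full echo of the run
    configuration, the tool version and the bootstrap seed.
    """
    report = {
        "tool": "codexfit",
        "version": __version__,
        "seed": seed,
        "d_lat_m2_s": result.d_lat,
        "d_lat_1e12": result.d_lat_1e12,
        "ci95_m2_s": [result.ci95_low, result.ci95_high],
        "ci95_1e12": [result.ci95_low * 1e12, result.ci95_high * 1e12],
        "amplitude": result.amplitude,
        "residual_rms": result.residual_rms,
        "residuals": [float(r) for r in result.residuals],
        "converged": result.converged,
        "diagnostics": result.diagnostics,
        "config": config_echo or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    """Hex SHA-256 of a file, for reproducibility logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
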