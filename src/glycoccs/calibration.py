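"""Drift-time -> collision-cross-section calibration.

Traveling-wave ion-mobility drift times carry no absolute CCS scale, so
analyte CCSs are obtained from a standard curve fitted on calibrant
species of known CCS — here doubly protonated polyalanine oligomers.
The curve is an ordinary least-squares straight line

    CCS (Å²) = slope (Å²/ms) · t (ms) + intercept (Å²)

fitted without per-point weights.  Internal values are kept at full
precision; rounding to integer Å² (as conventional in published tables)
happens only in report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError, ParseError


@dataclass(frozen=True)
class CalibrantSeries:
    """Calibrant records: species ids, m/z, drift times (ms), reference CCS (Å²)."""

    species: tuple[str, ...]
    mz: tuple[float, ...]
    drift_ms: tuple[float, ...]
    ccs_A2: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.species)
        if not (len(self.mz) == len(self.drift_ms) == len(self.ccs_A2) == n):
            raise CalibrationError("calibrant series fields must have equal length")
        if n < 2:
            raise CalibrationError(f"need at least 2 calibrants, got {n}")
        t = np.asarray(self.drift_ms, dtype=float)
        if np.any(t <= 0):
            raise CalibrationError("drift times must be strictly positive")
        if np.allclose(t, t[0]):
            raise CalibrationError("all drift times identical; calibration line is singular")

    def __len__(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line: slope (Å²/ms), intercept (Å²), coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError(f"R² = {self.r_squared} outside [0, 1]")
        if self.n_points < 2:
            raise CalibrationError("a calibration needs at least two points")


def fit_calibration(series: CalibrantSeries) -> CalibrationModel:
    """Ordinary least-squares fit of reference CCS against drift time.

    Minimizes squared CCS residuals (drift time is the noise-free
    regressor); R² is the standard coefficient of determination.
    """
    t = np.asarray(series.drift_ms, dtype=float)
    c = np.asarray(series.ccs_A2, dtype=float)
    tbar, cbar = t.mean(), c.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0.0:
        raise CalibrationError("all drift times identical; calibration line is singular")
    slope = float(((t - tbar) * (c - cbar)).sum() / sxx)
    intercept = float(cbar - slope * tbar)
    resid = c - (slope * t + intercept)
    sst = float(((c - cbar) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - float((resid ** 2).sum()) / sst
    return CalibrationModel(slope=slope, intercept=intercept,
                            r_squared=min(max(r2, 0.0), 1.0), n_points=len(series))


def apply_calibration(model: CalibrationModel, drift_times: Sequence[float]) -> np.ndarray:
    """CCS_i = slope · t_i + intercept, at full precision (round only for display)."""
    t = np.asarray(drift_times, dtype=float)
    if np.any(t < 0):
        raise DomainError("drift times must be non-negative")
    return model.slope * t + model.intercept


def calibration_report(model: CalibrationModel, series: CalibrantSeries) -> pd.DataFrame:
    """Per-calibrant residual table (machine-readable; render with to_string)."""
    fitted = apply_calibration(model, series.drift_ms)
    df = pd.DataFrame({
        "species": series.species,
        "mz": series.mz,
        "drift_ms": series.drift_ms,
        "ccs_ref_A2": series.ccs_A2,
        "ccs_fit_A2": fitted,
        "residual_A2": np.asarray(series.ccs_A2) - fitted,
    })
    df.attrs["slope_A2_per_ms"] = model.slope
    df.attrs["intercept_A2"] = model.intercept
    df.attrs["r_squared"] = model.r_squared
    df.attrs["n_points"] = model.n_points
    return df


def read_calibrant_table(path: str | Path) -> CalibrantSeries:
    """Read a delimited calibrant table with header (species, mz, drift_ms, ccs_A2)."""
    df = _read_table(path, required=("species", "mz", "drift_ms", "ccs_A2"))
    return CalibrantSeries(
        species=tuple(df["species"].astype(str)),
        mz=tuple(df["mz"].astype(float)),
        drift_ms=tuple(df["drift_ms"].astype(float)),
        ccs_A2=tuple(df["ccs_A2"].astype(float)),
    )


def read_analyte_table(path: str | Path) -> pd.DataFrame:
    """Read an analyte drift-time table with header (species, mz, drift_ms)."""
    return _read_table(path, required=("species", "mz", "drift_ms"))


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"table {path} missing columns {missing}; found {list(df.columns)}")
    return df
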