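"""Database-wide screening: target properties A/R/P, ranking, histograms,
and per-mode orientation maps.

The target properties sum per-mode intensities over the set *M* of normal
modes whose (scaled) frequencies fall in a user-chosen window [lo, hi]:

    A = Σ_{m∈M} I_m^A      (IR)
    R = Σ_{m∈M} I_m^R      (Raman)
    P = Σ_{m∈M} I_m^c      (SFG / upconversion)

using either orientation-averaged or orientation-specific per-mode values.
Raw values span orders of magnitude across a compound library, so scores for
cross-molecule comparison are z-scores of log10(value + ε) with a small
data-derived offset ε; standardization is monotone, hence never changes the
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .averaging import average_intensity
from .intensities import mode_intensity
from .orientation import (
    EulerOrientation,
    FieldSetup,
    rotation_matrix,
    rotate_mode,
    rx,
    ry,
    rz,
)
from .vibrecord import MoleculeRecord, NormalMode, VibDatabase

TARGET_KIND = {"A": "ir", "R": "raman", "P": "sfg"}


@dataclass(frozen=True)
class ScreeningQuery:
    """Target property, frequency window, scaling, fields and orientation mode."""

    target: str
    window: tuple[float, float]
    fields: FieldSetup
    scaling: float = 1.0
    averaged: bool = True
    orientation: EulerOrientation = field(default_factory=EulerOrientation)

    def __post_init__(self) -> None:
        if self.target not in TARGET_KIND:
            raise ValueError(f"target must be one of {sorted(TARGET_KIND)}, got {self.target!r}")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window must satisfy lo < hi, got {self.window}")
        if self.scaling <= 0:
            raise ValueError(f"scaling must be positive, got {self.scaling}")


@dataclass(frozen=True)
class ScreeningTable:
    """Per-molecule raw target values, standardized scores and ranks."""

    frame: pd.DataFrame  # columns: id, value, score, rank

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.frame.head(k)


def target_value(rec: MoleculeRecord, q: ScreeningQuery) -> float:
    """Sum of per-mode intensities over the window (on the scaled axis).

    The scaling factor is applied to the mode wavenumber consistently: both
    for window membership (closed interval, boundary ties included) and
    inside the Raman/SFG wavenumber prefactors.  An empty mode set gives 0.
    """
    kind = TARGET_KIND[q.target]
    lo, hi = q.window
    r = None if q.averaged else rotation_matrix(q.orientation)
    total = 0.0
    for m in rec.modes:
        nu = m.wavenumber * q.scaling
        if not lo <= nu <= hi:
            continue
        scaled = replace_wavenumber(m, nu)
        if q.averaged:
            total += average_intensity(scaled, q.fields, kind)
        else:
            total += mode_intensity(rotate_mode(scaled, r), q.fields, kind)
    return total


def replace_wavenumber(m: NormalMode, wavenumber: float) -> NormalMode:
    return NormalMode(
        index=m.index,
        wavenumber=wavenumber,
        dipole_derivative=m.dipole_derivative,
        polarizability_derivative=m.polarizability_derivative,
    )


def standardize(values) -> np.ndarray:
    """z-scores of log10(value + ε), ε = smallest positive value / 100.

    Zero-variance input (including all-zero) maps to all-zero scores.
    Monotone in the raw values, so score ranks equal raw-value ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    positive = values[values > 0]
    if positive.size == 0:
        return np.zeros_like(values)
    eps = positive.min() / 100.0
    logs = np.log10(values + eps)
    sd = logs.std()
    if sd == 0:
        return np.zeros_like(values)
    return (logs - logs.mean()) / sd


def rank_database(db: VibDatabase, q: ScreeningQuery) -> ScreeningTable:
    """One row per molecule, sorted by decreasing raw value; ties break by id."""
    ids = [rec.id for rec in db.records]
    raw = np.array([target_value(rec, q) for rec in db.records])
    scores = standardize(raw)
    frame = pd.DataFrame({"id": ids, "value": raw, "score": scores})
    frame = frame.sort_values(
        ["value", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return ScreeningTable(frame=frame)


def histogram(values, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and counts; log-spaced bins when all values are positive."""
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.linspace(0.0, 1.0, n_bins + 1), np.zeros(n_bins, dtype=int)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin > 0 and vmax > vmin:
        edges = np.geomspace(vmin, vmax, n_bins + 1)
    elif vmax > vmin:
        edges = np.linspace(vmin, vmax, n_bins + 1)
    else:  # all values identical
        pad = abs(vmin) * 0.5 + 0.5
        edges = np.linspace(vmin - pad, vmax + pad, n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


_AXIS_ROT = {"x": rx, "y": ry, "z": rz}


def axis_rotation(axis: str, angle: float) -> np.ndarray:
    """Proper rotation by ``angle`` about a Cartesian axis x, y or z."""
    try:
        return _AXIS_ROT[axis.lower()](angle)
    except KeyError:
        raise ValueError(f"axis must be x, y or z, got {axis!r}") from None


def orientation_map(
    m: NormalMode,
    axis: str,
    fields: FieldSetup,
    kind: str,
    n_angles: int = 72,
) -> np.ndarray:
    """Intensity of a mode rotated about one axis, sampled on [0, 2π).

    Returns an ``(n_angles, 2)`` array of (angle, intensity) rows — the polar
    diagram of the mode's response projected on the plane perpendicular to
    the rotation axis.
    """
    if n_angles < 4:
        raise ValueError(f"n_angles must be >= 4, got {n_angles}")
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    out = np.empty((n_angles, 2))
    for i, a in enumerate(angles):
        rotated = rotate_mode(m, axis_rotation(axis, a))
        out[i] = (a, mode_intensity(rotated, fields, kind))
    return out
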