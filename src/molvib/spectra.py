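"""Stick and broadened IR / Raman / SFG spectra.

IR and Raman sticks are broadened with *area-normalized* Lorentzians, so the
integral of each broadened band equals the stick intensity.  The SFG line
shape is the product of the IR and Raman Lorentzians — the mode converts an
IR photon through its Raman response, so the band inherits both widths; the
product shape is *peak-normalized* so the curve's maximum at the mode
position equals the stick SFG coefficient (a product of two unit-area
Lorentzians has no natural area convention).

A global multiplicative frequency scaling can be applied to stick positions
before plotting or window selection, the usual correction for the systematic
overestimation of harmonic wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .averaging import average_intensity
from .intensities import mode_intensity
from .orientation import EulerOrientation, FieldSetup, rotation_matrix, rotate_mode
from .vibrecord import MoleculeRecord


@dataclass(frozen=True)
class StickSpectrum:
    """Discrete spectrum: mode positions (cm^-1) and per-mode intensities."""

    kind: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float).ravel())
        object.__setattr__(self, "heights", np.asarray(self.heights, float).ravel())
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have equal length")
        if np.any(self.positions <= 0):
            raise ValueError("stick positions must be strictly positive")


@dataclass(frozen=True)
class BroadenedSpectrum:
    """Continuous spectrum on a uniform wavenumber grid."""

    kind: str
    grid: np.ndarray
    values: np.ndarray
    fwhm_ir: float | None = None
    fwhm_r: float | None = None

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


def stick_spectrum(
    rec: MoleculeRecord,
    kind: str,
    fields: FieldSetup,
    orientation: EulerOrientation | None = None,
    averaged: bool = False,
) -> StickSpectrum:
    """Per-mode stick spectrum of a record, orientation-specific or averaged."""
    modes = rec.modes
    if averaged:
        heights = [average_intensity(m, fields, kind) for m in modes]
    else:
        if orientation is not None:
            r = rotation_matrix(orientation)
            modes = [rotate_mode(m, r) for m in modes]
        heights = [mode_intensity(m, fields, kind) for m in modes]
    return StickSpectrum(
        kind=kind,
        positions=np.array([m.wavenumber for m in rec.modes]),
        heights=np.array(heights),
    )


def apply_frequency_scaling(sticks: StickSpectrum, s: float) -> StickSpectrum:
    """Multiply all stick positions by s > 0 (heights unchanged).

    Scaling is applied *before* any frequency-range masking, so a window is
    always interpreted on the scaled axis.
    """
    if s <= 0:
        raise ValueError(f"frequency scaling factor must be positive, got {s}")
    return replace(sticks, positions=sticks.positions * s)


def default_grid(sticks: StickSpectrum, fwhm: float, spacing: float = 1.0) -> np.ndarray:
    """Uniform grid covering the sticks with a 5·fwhm margin."""
    lo = max(0.0, float(sticks.positions.min()) - 5.0 * fwhm)
    hi = float(sticks.positions.max()) + 5.0 * fwhm
    return np.arange(lo, hi + spacing, spacing)


def _unit_area_lorentzian(x: np.ndarray, gamma: float) -> np.ndarray:
    return (gamma / np.pi) / (x * x + gamma * gamma)


def broaden(sticks: StickSpectrum, fwhm: float, grid: np.ndarray) -> BroadenedSpectrum:
    """Sum of unit-area Lorentzians: band integral equals stick intensity.

    ``values(ν) = Σ_m h_m · (γ/π)/((ν − ν_m)² + γ²)`` with ``γ = fwhm/2``.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    grid = np.asarray(grid, float)
    gamma = fwhm / 2.0
    diff = grid[:, None] - sticks.positions[None, :]
    values = _unit_area_lorentzian(diff, gamma) @ sticks.heights
    return BroadenedSpectrum(kind=sticks.kind, grid=grid, values=values, fwhm_r=fwhm)


def sfg_lineshape(
    sticks: StickSpectrum, fwhm_ir: float, fwhm_r: float, grid: np.ndarray
) -> BroadenedSpectrum:
    """SFG spectrum: per mode, the product of unit-peak IR and Raman Lorentzians.

    ``shape(ν) = [γ_A²/((ν−ν_m)²+γ_A²)] · [γ_R²/((ν−ν_m)²+γ_R²)]`` — both
    factors centred at the (scaled) mode position — scaled so the curve's
    peak at ν_m equals the stick SFG coefficient.  For equal widths w the
    product shape has fwhm ``w·√(√2 − 1) ≈ 0.6436·w``.
    """
    if fwhm_ir <= 0 or fwhm_r <= 0:
        raise ValueError("both fwhm values must be positive")
    grid = np.asarray(grid, float)
    ga, gr = fwhm_ir / 2.0, fwhm_r / 2.0
    diff2 = (grid[:, None] - sticks.positions[None, :]) ** 2
    shape = (ga * ga / (diff2 + ga * ga)) * (gr * gr / (diff2 + gr * gr))
    values = shape @ sticks.heights
    return BroadenedSpectrum(
        kind=sticks.kind, grid=grid, values=values, fwhm_ir=fwhm_ir, fwhm_r=fwhm_r
    )
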