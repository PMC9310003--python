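"""Orientation-specific per-mode IR, Raman and SFG intensities.

For a normal mode *m* with dipole derivative μ′ (e·amu^-1/2) and symmetric
polarizability derivative ᾱ′ (bohr²·amu^-1/2):

* IR absorption intensity (km/mol):
  ``I_m^A = C_A · |e_IR · μ′|²``

* Stokes differential Raman cross-section (cm²/sr), Placzek form with a
  thermal-occupancy prefactor:
  ``I_m^R = C_R · (ν̅_R − ν̅_m)⁴ / ν̅_m · n(ν̅_m, T) · |e_out · ᾱ′ · e_in|²``
  where ``n(ν̅, T) = 1/(1 − exp(−hc·ν̅/kT))``.

* SFG (IR-to-visible upconversion) coefficient, measuring the net increase
  in anti-Stokes Raman intensity under IR pumping — hence the *plus* sign
  in the wavenumber factor and *no* occupancy factor:
  ``I_m^c = C · (ν̅_R + ν̅_m)⁴ / ν̅_m · |e_IR·μ′|² · |e_out·ᾱ′·e_in|²``

All three are squared real contractions and therefore non-negative; IR is
independent of ν̅_m and T, SFG is independent of T.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import C, C_A, C_R, HC_OVER_K
from .orientation import FieldSetup, _axis_vector
from .vibrecord import NormalMode

KINDS = ("ir", "raman", "sfg")


def thermal_occupancy(wavenumber: float, temperature: float) -> float:
    """Bose factor ``1/(1 − exp(−hc·ν̅/kT))``; exactly 1 at T = 0."""
    if wavenumber <= 0:
        raise ValueError(f"wavenumber must be positive, got {wavenumber}")
    if temperature < 0:
        raise ValueError(f"temperature must be non-negative, got {temperature}")
    if temperature == 0.0:
        return 1.0
    x = HC_OVER_K * wavenumber / temperature
    return 1.0 / (1.0 - math.exp(-x))


def ir_projection(m: NormalMode, e_ir) -> float:
    """Squared field projection ``|e_IR · μ′|²`` (atomic units)."""
    e = _axis_vector(e_ir)
    return float(np.dot(e, m.dipole_derivative)) ** 2


def raman_contraction(m: NormalMode, e_in, e_out) -> float:
    """Bare squared tensor contraction ``|e_out · ᾱ′ · e_in|²`` (bohr⁴/amu)."""
    ein = _axis_vector(e_in)
    eout = _axis_vector(e_out)
    return float(eout @ m.polarizability_derivative @ ein) ** 2


def raman_prefactor(wavenumber: float, f: FieldSetup, stokes: bool = True) -> float:
    """Wavenumber/thermal prefactor of the Raman (or SFG) cross-section.

    Stokes: ``C_R (ν̅_R − ν̅_m)⁴/ν̅_m · n(ν̅_m, T)``; for the upconversion
    (anti-Stokes-like) factor use ``stokes=False``: ``(ν̅_R + ν̅_m)⁴/ν̅_m``
    with no occupancy (the C_A factor is applied separately).
    """
    if stokes:
        if f.pump_wavenumber <= wavenumber:
            raise ValueError(
                f"Stokes regime requires pump wavenumber > mode wavenumber "
                f"({f.pump_wavenumber} <= {wavenumber})"
            )
        return (
            C_R
            * (f.pump_wavenumber - wavenumber) ** 4
            / wavenumber
            * thermal_occupancy(wavenumber, f.temperature)
        )
    return C_R * (f.pump_wavenumber + wavenumber) ** 4 / wavenumber


def ir_intensity(m: NormalMode, e_ir) -> float:
    """IR absorption intensity ``C_A |e_IR·μ′|²`` in km/mol."""
    return C_A * ir_projection(m, e_ir)


def raman_intensity(m: NormalMode, f: FieldSetup, bare: bool = False) -> float:
    """Stokes differential Raman cross-section in cm²/sr.

    With ``bare=True``, returns only the squared contraction
    ``|e_out·ᾱ′·e_in|²`` (the Raman "activity"-like quantity, bohr⁴/amu).
    """
    contraction = raman_contraction(m, f.e_in, f.e_out)
    if bare:
        return contraction
    return raman_prefactor(m.wavenumber, f, stokes=True) * contraction


def sfg_intensity(m: NormalMode, f: FieldSetup) -> float:
    """SFG upconversion coefficient (product units, km·mol^-1·cm²·sr^-1 scale)."""
    return (
        C_A
        * raman_prefactor(m.wavenumber, f, stokes=False)
        * ir_projection(m, f.e_ir)
        * raman_contraction(m, f.e_in, f.e_out)
    )


def mode_intensity(m: NormalMode, f: FieldSetup, kind: str) -> float:
    """Dispatch on ``kind`` in {'ir', 'raman', 'sfg'} (orientation-specific)."""
    kind = kind.lower()
    if kind == "ir":
        return ir_intensity(m, f.e_ir)
    if kind == "raman":
        return raman_intensity(m, f)
    if kind == "sfg":
        return sfg_intensity(m, f)
    raise ValueError(f"unknown intensity kind {kind!r}; expected one of {KINDS}")
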