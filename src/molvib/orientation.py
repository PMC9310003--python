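"""Rotations, surface alignment, and field-polarization handling.

The molecular orientation is parametrized by Euler angles (ϕ, θ, ξ) in the
intrinsic z-y-z convention, composed as ``R = Rz(ϕ) · Ry(θ) · Rz(ξ)``.
Molecules bound through a thiol sulfur are conventionally aligned with the
S–Au bond along +z (the surface normal), Au at the origin.

A :class:`FieldSetup` holds the three field polarization unit vectors
(IR beam, Raman pump "in", Raman scattered "out"), the pump wavenumber and
the temperature.  Defaults follow common surface-enhanced practice: all
fields along z, 785 nm pump, 298.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import wavelength_nm_to_wavenumber
from .vibrecord import MoleculeRecord, NormalMode

ORTHOGONALITY_TOL = 1e-10

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}

DEFAULT_PUMP_WAVENUMBER = wavelength_nm_to_wavenumber(785.0)  # cm^-1
DEFAULT_TEMPERATURE = 298.15  # K


@dataclass(frozen=True)
class EulerOrientation:
    """Intrinsic z-y-z Euler angles (radians) rotating a molecule."""

    phi: float = 0.0
    theta: float = 0.0
    xi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi", "theta", "xi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_degrees(cls, phi: float, theta: float, xi: float) -> "EulerOrientation":
        return cls(math.radians(phi), math.radians(theta), math.radians(xi))


def _axis_vector(p: "str | np.ndarray") -> np.ndarray:
    if isinstance(p, str):
        try:
            return _AXES[p.lower()].copy()
        except KeyError:
            raise ValueError(f"unknown polarization axis {p!r}; use x, y or z") from None
    v = np.asarray(p, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-12:
        raise ValueError(f"polarization vector {v} is not unit norm (|v| = {n})")
    return v


@dataclass(frozen=True)
class FieldSetup:
    """Polarizations of the IR, Raman-in and Raman-out fields plus pump/T."""

    e_ir: np.ndarray
    e_in: np.ndarray
    e_out: np.ndarray
    pump_wavenumber: float = DEFAULT_PUMP_WAVENUMBER
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("e_ir", "e_in", "e_out"):
            object.__setattr__(self, name, _axis_vector(getattr(self, name)))
        if self.pump_wavenumber <= 0:
            raise ValueError(f"pump wavenumber must be positive, got {self.pump_wavenumber}")
        if self.temperature < 0:
            raise ValueError(f"temperature must be non-negative, got {self.temperature}")

    @classmethod
    def from_axes(
        cls,
        e_ir: str = "z",
        e_in: str = "z",
        e_out: str = "z",
        pump_wavenumber: float = DEFAULT_PUMP_WAVENUMBER,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "FieldSetup":
        return cls(e_ir, e_in, e_out, pump_wavenumber, temperature)


def rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(o: EulerOrientation) -> np.ndarray:
    """Proper rotation ``R = Rz(ϕ) @ Ry(θ) @ Rz(ξ)``."""
    return rz(o.phi) @ ry(o.theta) @ rz(o.xi)


def _check_rotation(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float).reshape(3, 3)
    if not np.allclose(r @ r.T, np.eye(3), atol=ORTHOGONALITY_TOL):
        raise ValueError("matrix is not orthogonal")
    if np.linalg.det(r) < 0:
        raise ValueError("matrix is a reflection, not a proper rotation")
    return r


def rotate_mode(m: NormalMode, r: np.ndarray) -> NormalMode:
    """Co-rotate a mode's tensors: μ′ → R·μ′, ᾱ′ → R·ᾱ′·Rᵀ."""
    r = _check_rotation(r)
    return NormalMode(
        index=m.index,
        wavenumber=m.wavenumber,
        dipole_derivative=r @ m.dipole_derivative,
        polarizability_derivative=r @ m.polarizability_derivative @ r.T,
    )


def rotate_fields(f: FieldSetup, r: np.ndarray) -> FieldSetup:
    """Co-rotate all three polarization vectors by the same rotation."""
    r = _check_rotation(r)
    return replace(f, e_ir=r @ f.e_ir, e_in=r @ f.e_in, e_out=r @ f.e_out)


def rotate_record(rec: MoleculeRecord, r: np.ndarray) -> MoleculeRecord:
    """Rigidly rotate geometry and co-rotate every mode."""
    r = _check_rotation(r)
    return MoleculeRecord(
        id=rec.id,
        smiles=rec.smiles,
        elements=list(rec.elements),
        coordinates=rec.coordinates @ r.T,
        modes=[rotate_mode(m, r) for m in rec.modes],
        provenance=dict(rec.provenance),
    )


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Smallest proper rotation taking unit vector v onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])  # rotate π about x
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def align_to_surface(rec: MoleculeRecord, anchor: tuple[int, int]) -> MoleculeRecord:
    """Rigidly place a record in the surface frame.

    The first anchor atom (typically Au) is translated to the origin and the
    anchor→second (typically Au→S) vector is rotated onto +z; all modes are
    co-rotated.  Bond lengths are preserved.
    """
    i, j = anchor
    n = len(rec.elements)
    if not (0 <= i < n and 0 <= j < n) or i == j:
        raise IndexError(f"invalid anchor pair {anchor} for {n} atoms")
    origin = rec.coordinates[i]
    axis = rec.coordinates[j] - origin
    d = np.linalg.norm(axis)
    if d < 1e-9:
        raise ValueError(f"anchor atoms {anchor} are coincident: degenerate axis")
    r = _rotation_to_z(axis / d)
    coords = (rec.coordinates - origin) @ r.T
    return MoleculeRecord(
        id=rec.id,
        smiles=rec.smiles,
        elements=list(rec.elements),
        coordinates=coords,
        modes=[rotate_mode(m, r) for m in rec.modes],
        provenance=dict(rec.provenance),
    )


def find_anchor(rec: MoleculeRecord) -> tuple[int, int]:
    """Default surface anchor: (Au, S) if Au present, else (S, nearest heavy atom)."""
    elements = [e.capitalize() for e in rec.elements]
    if "Au" in elements and "S" in elements:
        return elements.index("Au"), elements.index("S")
    if "S" in elements:
        s = elements.index("S")
        heavy = [
            k for k, e in enumerate(elements) if k != s and e != "H"
        ]
        if heavy:
            d = np.linalg.norm(rec.coordinates[heavy] - rec.coordinates[s], axis=1)
            return s, heavy[int(np.argmin(d))]
    raise ValueError(f"record '{rec.id}': no Au–S or S–heavy anchor found")
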