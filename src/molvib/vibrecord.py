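"""Domain data model and JSON interchange I/O for vibrational records.

A :class:`MoleculeRecord` bundles identity (SMILES), geometry and the list
of normal modes; a :class:`VibDatabase` is a labelled collection of records
and is the screening unit.  Databases are serialized as a single
self-describing JSON document (schema key ``vibrecord/1``) with all numbers
at full double precision.

Units are fixed by the schema: wavenumbers in cm^-1, dipole derivatives in
e·amu^-1/2, polarizability derivatives in bohr²·amu^-1/2, coordinates in Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np

SCHEMA = "vibrecord/1"

#: relative tolerance for the symmetry of polarizability-derivative tensors
SYMMETRY_RTOL = 1e-12


@dataclass
class NormalMode:
    """One vibrational normal mode.

    Parameters
    ----------
    index : int
        Ordinal of the mode within its molecule.
    wavenumber : float
        Harmonic wavenumber ν̅_m in cm^-1 (must be positive for a valid mode).
    dipole_derivative : (3,) array
        μ′_m in e·amu^-1/2.
    polarizability_derivative : (3, 3) array
        ᾱ′_m in bohr²·amu^-1/2; symmetric, so its squared contraction is in
        bohr⁴·amu^-1.
    """

    index: int
    wavenumber: float
    dipole_derivative: np.ndarray
    polarizability_derivative: np.ndarray

    def __post_init__(self) -> None:
        self.dipole_derivative = np.asarray(self.dipole_derivative, dtype=float).reshape(3)
        self.polarizability_derivative = np.asarray(
            self.polarizability_derivative, dtype=float
        ).reshape(3, 3)
        self.wavenumber = float(self.wavenumber)


@dataclass
class MoleculeRecord:
    """Identity, geometry and normal modes of one molecule."""

    id: str
    smiles: str
    elements: list[str]
    coordinates: np.ndarray
    modes: list[NormalMode]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)


@dataclass
class VibDatabase:
    """A labelled collection of molecule records; record ids are unique."""

    records: list[MoleculeRecord]
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def get(self, rec_id: str) -> MoleculeRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


def _symmetry_defect(t: np.ndarray) -> float:
    scale = max(float(np.abs(t).max()), 1e-300)
    return float(np.abs(t - t.T).max()) / scale


def validate_mode(mode: NormalMode, prefix: str = "mode") -> list[str]:
    """Return human-readable invariant violations for one mode (never raises)."""
    out: list[str] = []
    tag = f"{prefix}[{mode.index}]"
    if not np.isfinite(mode.wavenumber) or mode.wavenumber <= 0:
        out.append(f"{tag}.wavenumber: must be positive, got {mode.wavenumber}")
    if not np.all(np.isfinite(mode.dipole_derivative)):
        out.append(f"{tag}.dipole_derivative: non-finite entries")
    if not np.all(np.isfinite(mode.polarizability_derivative)):
        out.append(f"{tag}.polarizability_derivative: non-finite entries")
    elif _symmetry_defect(mode.polarizability_derivative) > SYMMETRY_RTOL:
        out.append(
            f"{tag}.polarizability_derivative: not symmetric "
            f"(relative defect {_symmetry_defect(mode.polarizability_derivative):.3g} "
            f"> {SYMMETRY_RTOL})"
        )
    return out


def validate_record(rec: MoleculeRecord) -> list[str]:
    """Return the list of invariant violations of a record; empty iff valid.

    Total function: arbitrary well-typed input yields violations as data,
    never an exception.
    """
    out: list[str] = []
    n_atoms = len(rec.elements)
    if rec.coordinates.shape != (n_atoms, 3):
        out.append(
            f"coordinates: expected shape ({n_atoms}, 3) to match elements, "
            f"got {rec.coordinates.shape}"
        )
    idx = [m.index for m in rec.modes]
    if len(set(idx)) != len(idx):
        out.append("modes: mode indices are not unique")
    elif idx != sorted(idx):
        out.append("modes: mode indices are not sorted")
    if n_atoms and len(rec.modes) > 3 * n_atoms:
        out.append(f"modes: {len(rec.modes)} modes exceed 3N = {3 * n_atoms}")
    for m in rec.modes:
        out.extend(validate_mode(m, prefix=f"record '{rec.id}' mode"))
    return out


class SchemaError(ValueError):
    """Raised when an interchange document does not conform to the schema."""


def _mode_to_json(m: NormalMode) -> dict[str, Any]:
    return {
        "index": int(m.index),
        "wavenumber_cm1": m.wavenumber,
        "dipole_derivative_au": m.dipole_derivative.tolist(),
        "polarizability_derivative_au": m.polarizability_derivative.tolist(),
    }


def _record_to_json(rec: MoleculeRecord) -> dict[str, Any]:
    return {
        "id": rec.id,
        "smiles": rec.smiles,
        "elements": list(rec.elements),
        "coordinates": rec.coordinates.tolist(),
        "modes": [_mode_to_json(m) for m in rec.modes],
        "provenance": rec.provenance,
    }


def _mode_from_json(obj: dict[str, Any], where: str) -> NormalMode:
    try:
        return NormalMode(
            index=int(obj["index"]),
            wavenumber=float(obj["wavenumber_cm1"]),
            dipole_derivative=np.array(obj["dipole_derivative_au"], dtype=float),
            polarizability_derivative=np.array(
                obj["polarizability_derivative_au"], dtype=float
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: malformed mode entry ({exc})") from exc


def _record_from_json(obj: dict[str, Any], pos: int) -> MoleculeRecord:
    where = f"record #{pos}"
    try:
        rec_id = str(obj["id"])
        where = f"record '{rec_id}'"
        rec = MoleculeRecord(
            id=rec_id,
            smiles=str(obj["smiles"]),
            elements=[str(e) for e in obj["elements"]],
            coordinates=np.array(obj["coordinates"], dtype=float).reshape(-1, 3),
            modes=[_mode_from_json(m, where) for m in obj["modes"]],
            provenance=dict(obj.get("provenance", {})),
        )
    except SchemaError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: malformed record ({exc})") from exc
    return rec


def read_records(path: str | Path) -> VibDatabase:
    """Read a ``vibrecord/1`` JSON interchange file.

    Raises
    ------
    SchemaError
        If the document is malformed (names the offending record/field).
    ValueError
        If a record violates a type invariant (e.g. asymmetric tensor
        beyond tolerance, non-positive wavenumber).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA:
        raise SchemaError(f"{path}: not a {SCHEMA} document")
    records = [_record_from_json(o, i) for i, o in enumerate(doc.get("records", []))]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicate record ids {dup}")
    problems: list[str] = []
    for rec in records:
        problems.extend(validate_record(rec))
    if problems:
        raise ValueError("validation failed:\n" + "\n".join(problems))
    return VibDatabase(records=records, label=str(doc.get("label", "")))


def write_records(db: VibDatabase, path: str | Path) -> None:
    """Write a database as a ``vibrecord/1`` JSON document (full precision)."""
    doc = {
        "schema": SCHEMA,
        "label": db.label,
        "records": [_record_to_json(r) for r in db.records],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
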