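"""Deterministic synthetic vibrational records for testing and examples.

The generator emulates the *structure* of quantum-chemistry frequency
output for thiol-on-gold compounds — positive wavenumbers, dipole-derivative
3-vectors, symmetric polarizability-derivative tensors, an Au–S anchor
geometry aligned to +z — at realistic orders of magnitude, without any claim
of mimicking real intensity distributions.

Random streams are per-record (a counter-based generator keyed by the seed
and the record index), so taking a subset of a database never reshuffles the
remaining records' values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vibrecord import MoleculeRecord, NormalMode, VibDatabase

AU_S_BOND = 2.35  # Å, typical Au–S bond length


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic database.

    Defaults are order-of-magnitude realistic for organic thiols: mid-IR
    wavenumbers, dipole derivatives giving IR intensities of O(1–100) km/mol
    and polarizability derivatives giving typical Raman activities.
    """

    n_molecules: int = 10
    modes_per_molecule: tuple[int, int] = (6, 30)
    wavenumber_range: tuple[float, float] = (100.0, 3600.0)
    dipole_scale: float = 0.1  # e·amu^-1/2 per component
    polarizability_scale: float = 3.0  # bohr²·amu^-1/2 per component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        lo, hi = self.modes_per_molecule
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid modes_per_molecule range {self.modes_per_molecule}")
        wlo, whi = self.wavenumber_range
        if wlo <= 0 or whi < wlo:
            raise ValueError(f"invalid wavenumber_range {self.wavenumber_range}")


CC_BOND = 1.54  # Å, sp3 C–C bond length


def _random_symmetric(rng: np.random.Generator, scale: float) -> np.ndarray:
    t = rng.normal(scale=scale, size=(3, 3))
    return (t + t.T) / 2.0


def _thiol_geometry(n_modes: int) -> tuple[list[str], np.ndarray]:
    """Au–S anchor on +z plus a carbon backbone long enough that 3N ≥ modes."""
    n_carbons = max(0, -(-n_modes // 3) - 2)
    elements = ["Au", "S"] + ["C"] * n_carbons
    z = [0.0, AU_S_BOND] + [AU_S_BOND + CC_BOND * (k + 1) for k in range(n_carbons)]
    coords = np.zeros((len(elements), 3))
    coords[:, 2] = z
    return elements, coords


def _make_record(spec: SynthSpec, index: int) -> MoleculeRecord:
    rng = np.random.default_rng([spec.seed, index])
    lo, hi = spec.modes_per_molecule
    n_modes = int(rng.integers(lo, hi + 1))
    wavenumbers = np.sort(rng.uniform(*spec.wavenumber_range, size=n_modes))
    modes = [
        NormalMode(
            index=k,
            wavenumber=float(wavenumbers[k]),
            dipole_derivative=rng.normal(scale=spec.dipole_scale, size=3),
            polarizability_derivative=_random_symmetric(rng, spec.polarizability_scale),
        )
        for k in range(n_modes)
    ]
    elements, coords = _thiol_geometry(n_modes)
    return MoleculeRecord(
        id=f"synth-{index:05d}",
        smiles="C" * (len(elements) - 2) + "S[Au]" if len(elements) > 2 else "S[Au]",
        elements=elements,
        coordinates=coords,
        modes=modes,
        provenance={"generator": "molvib.synthgen", "seed": spec.seed, "index": index},
    )


def generate(spec: SynthSpec) -> VibDatabase:
    """Generate a fully reproducible synthetic database from a spec."""
    records = [_make_record(spec, i) for i in range(spec.n_molecules)]
    return VibDatabase(records=records, label=f"synthetic(seed={spec.seed})")


def scale_record(rec: MoleculeRecord, factor: float, new_id: str) -> MoleculeRecord:
    """Copy of a record with every mode tensor multiplied by ``factor``."""
    return MoleculeRecord(
        id=new_id,
        smiles=rec.smiles,
        elements=list(rec.elements),
        coordinates=rec.coordinates.copy(),
        modes=[
            NormalMode(
                index=m.index,
                wavenumber=m.wavenumber,
                dipole_derivative=factor * m.dipole_derivative,
                polarizability_derivative=factor * m.polarizability_derivative,
            )
            for m in rec.modes
        ],
        provenance=dict(rec.provenance, scaled_by=factor),
    )


def with_dominant_record(
    db: VibDatabase, factor: float = 10.0, rec_id: str = "dominant"
) -> VibDatabase:
    """Append a constructed-dominance record to a database.

    The record carries a copy of *every* mode in the database with all
    tensors multiplied by ``factor``; by additivity and non-negativity of
    the per-mode intensities its target value is at least ``factor²`` times
    any other record's, for every target, window and orientation.
    """
    pooled = [m for rec in db.records for m in rec.modes]
    pooled.sort(key=lambda m: m.wavenumber)
    modes = [
        NormalMode(
            index=k,
            wavenumber=m.wavenumber,
            dipole_derivative=factor * m.dipole_derivative,
            polarizability_derivative=factor * m.polarizability_derivative,
        )
        for k, m in enumerate(pooled)
    ]
    elements, coords = _thiol_geometry(len(modes))
    dominant = MoleculeRecord(
        id=rec_id,
        smiles="S[Au]",
        elements=elements,
        coordinates=coords,
        modes=modes,
        provenance={"generator": "molvib.synthgen", "fixture": "dominant", "factor": factor},
    )
    return VibDatabase(records=db.records + [dominant], label=db.label)


def _single_mode_record(rec_id: str, mu, alpha, wavenumber: float = 1000.0) -> MoleculeRecord:
    return MoleculeRecord(
        id=rec_id,
        smiles="S[Au]",
        elements=["Au", "S"],
        coordinates=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, AU_S_BOND]]),
        modes=[
            NormalMode(
                index=0,
                wavenumber=wavenumber,
                dipole_derivative=np.asarray(mu, float),
                polarizability_derivative=np.asarray(alpha, float),
            )
        ],
        provenance={"generator": "molvib.synthgen", "fixture": rec_id},
    )


def make_witness_fixtures() -> VibDatabase:
    """Hand-constructed records that pin qualitative averaging behaviour.

    * ``iso`` — isotropic Raman tensor (ᾱ′ = I): γ′² = 0, so crossed-field
      averaged Raman vanishes and the SFG average factorizes.
    * ``aniso`` — traceless ᾱ′ = diag(1, −1, 0): a′ = 0, γ′² = 3.
    * ``witness`` — μ′ = ẑ with ᾱ′ = diag(1, 0, 0): the joint orientation
      average of the IR×Raman product differs strongly from the product of
      the separate averages.
    * ``dominant`` — every tensor 10× the ``iso`` record's, for ranking tests.
    """
    iso = _single_mode_record("iso", [0.0, 0.0, 0.1], np.eye(3))
    aniso = _single_mode_record("aniso", [0.1, 0.0, 0.0], np.diag([1.0, -1.0, 0.0]))
    witness = _single_mode_record("witness", [0.0, 0.0, 1.0], np.diag([1.0, 0.0, 0.0]))
    dominant = scale_record(iso, 10.0, "dominant")
    return VibDatabase(records=[iso, aniso, witness, dominant], label="witness-fixtures")
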