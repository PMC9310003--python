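"""Surface-layer geometric descriptors and SMILES similarity search.

For a molecule anchored to a flat gold surface through its thiol sulfur
(S–Au along +z), two simple geometric quantities approximate monolayer
packing: the *layer height* — the z-extent of the van der Waals envelope,
an estimate of monolayer thickness — and the *XY projection* — the footprint
area of the vdW envelope on the surface plane.

Similarity search uses Tanimoto coefficients on hashed circular (Morgan)
fingerprints, radius 2, 2048 bits.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

from .vibrecord import MoleculeRecord, VibDatabase

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048

#: Bondi van der Waals radii (Å); Au from Bondi's metallic-set convention.
BONDI_RADII = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Te": 2.06, "I": 1.98, "Xe": 2.16,
    "Au": 1.66,
}


def vdw_radius(element: str) -> float:
    try:
        return BONDI_RADII[element.capitalize()]
    except KeyError:
        raise ValueError(f"no van der Waals radius tabulated for element {element!r}") from None


def layer_height(rec: MoleculeRecord, vdw: bool = True) -> float:
    """z-extent of the molecule (Å): max(z+r) − min(z−r) over atoms.

    With ``vdw=False`` only atom centers are used (bare z-extent).  Assumes
    the record is already in the surface frame (S–Au along z).
    """
    if len(rec.elements) == 0:
        raise ValueError(f"record '{rec.id}' has no atoms")
    z = rec.coordinates[:, 2]
    r = np.array([vdw_radius(e) for e in rec.elements]) if vdw else np.zeros(len(z))
    return float((z + r).max() - (z - r).min())


def xy_projection_area(rec: MoleculeRecord, resolution: float = 0.05, vdw: bool = True) -> float:
    """Footprint (Å²) of the union of atom disks projected on the xy plane.

    Rasterizes the union of vdW disks on a square grid of the given pixel
    size; ``vdw=False`` degenerates to zero area (point projection).
    """
    if len(rec.elements) == 0:
        raise ValueError(f"record '{rec.id}' has no atoms")
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if not vdw:
        return 0.0
    xy = rec.coordinates[:, :2]
    radii = np.array([vdw_radius(e) for e in rec.elements])
    lo = (xy - radii[:, None]).min(axis=0) - resolution
    hi = (xy + radii[:, None]).max(axis=0) + resolution
    xs = np.arange(lo[0], hi[0] + resolution, resolution)
    ys = np.arange(lo[1], hi[1] + resolution, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros(gx.shape, dtype=bool)
    for (cx, cy), r in zip(xy, radii):
        covered |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    return float(covered.sum()) * resolution * resolution


_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    return _GENERATOR.GetFingerprint(mol)


def similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto similarity of Morgan (radius-2, 2048-bit) fingerprints."""
    return float(TanimotoSimilarity(_fingerprint(smiles_a), _fingerprint(smiles_b)))


def search_similar(query: str, db: VibDatabase, k: int = 10) -> list[tuple[str, float]]:
    """Top-k records by similarity to the query SMILES.

    Descending by score with deterministic id tie-break; an exact match
    (score 1.0) sorts first.  Records whose SMILES do not parse are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    qfp = _fingerprint(query)
    hits: list[tuple[str, float]] = []
    for rec in db.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            continue
        hits.append((rec.id, float(TanimotoSimilarity(qfp, _GENERATOR.GetFingerprint(mol)))))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits[:k]
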