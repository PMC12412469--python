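"""Minimal heavy-atom view of a protein structure.

Wraps gemmi parsing of PDB/mmCIF into flat numpy arrays (coordinates,
van der Waals radii, residue labels) used both for building molecular
surfaces and for the post-alignment clash / interface-contact filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

# Bondi-style van der Waals radii (Å) for the elements common in
# protein heavy-atom models; anything exotic falls back to 1.7 Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70


@dataclass
class StructureAtoms:
    """Heavy atoms of one structure as flat arrays.

    Attributes
    ----------
    coords : (n, 3) float64
        Cartesian coordinates in Å, as deposited (no recentering).
    radii : (n,) float64
        Van der Waals radii in Å.
    residue_uid : (n,) object
        ``"chain:seqnum:resname"`` label per atom; used to count
        interfacial residues.
    is_ca : (n,) bool
        True for alpha-carbon atoms.
    source_id : str
        Free-form label, usually the file stem.
    """

    coords: np.ndarray
    radii: np.ndarray
    residue_uid: np.ndarray
    is_ca: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.is_ca = np.asarray(self.is_ca, dtype=bool)
        self.residue_uid = np.asarray(self.residue_uid, dtype=object)
        n = len(self.coords)
        if not (len(self.radii) == len(self.residue_uid) == len(self.is_ca) == n):
            raise ValueError("StructureAtoms arrays must have equal length")

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureAtoms":
        """Return a copy with coordinates mapped through x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float).reshape(3, 3)
        translation = np.asarray(translation, dtype=float).reshape(3)
        return StructureAtoms(
            coords=self.coords @ rotation.T + translation,
            radii=self.radii.copy(),
            residue_uid=self.residue_uid.copy(),
            is_ca=self.is_ca.copy(),
            source_id=self.source_id,
        )


def load_structure(path: str | Path, source_id: str | None = None) -> StructureAtoms:
    """Read heavy atoms from a PDB or mmCIF file.

    Hydrogens and waters are dropped.  Missing heavy atoms are not
    rebuilt; structures are taken as given (a warning is emitted when a
    polymer residue lacks an alpha carbon, the cheapest completeness
    proxy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    coords, radii, uids, is_ca = [], [], [], []
    n_missing_ca = 0
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            has_ca = False
            for atom in residue:
                if atom.element.name == "H":
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                element = atom.element.name.upper()
                radii.append(VDW_RADII.get(element, DEFAULT_VDW))
                uids.append(f"{chain.name}:{residue.seqid.num}:{residue.name}")
                is_ca.append(atom.name == "CA")
                has_ca = has_ca or atom.name == "CA"
            info = gemmi.find_tabulated_residue(residue.name)
            if info is not None and info.is_amino_acid() and not has_ca:
                n_missing_ca += 1
    if not coords:
        raise ValueError(f"no heavy atoms found in {path}")
    if n_missing_ca:
        warnings.warn(
            f"{path.name}: {n_missing_ca} amino-acid residue(s) lack a CA atom; "
            "structure used as-is",
            stacklevel=2,
        )
    return StructureAtoms(
        coords=np.array(coords),
        radii=np.array(radii),
        residue_uid=np.array(uids, dtype=object),
        is_ca=np.array(is_ca),
        source_id=source_id if source_id is not None else path.stem,
    )


def synthetic_helix(n_residues: int = 30, offset: np.ndarray | None = None,
                    source_id: str = "synthetic-helix") -> StructureAtoms:
    """Synthetic poly-alanine-like backbone helix for tests and demos.

    An idealized alpha-helical trace (rise 1.5 Å, 100 degrees per
    residue, radius 2.3 Å) carrying N, CA, C, O, CB pseudo-atoms.  Not a
    physically refined model; geometry is only meant to be protein-like
    at the 1 Å scale for clash/interface counting.
    """
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    names = ["N", "CA", "C", "O", "CB"]
    local = {
        "N": np.array([0.0, 0.0, -0.6]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.5, 0.5, 0.6]),
        "O": np.array([1.2, 0.9, 1.0]),
        "CB": np.array([-1.0, 0.9, 0.0]),
    }
    coords, radii, uids, is_ca = [], [], [], []
    for i in range(n_residues):
        angle = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
        for name in names:
            coords.append(ca + local[name] + offset)
            radii.append(VDW_RADII["N" if name == "N" else "O" if name == "O" else "C"])
            uids.append(f"A:{i + 1}:ALA")
            is_ca.append(name == "CA")
    return StructureAtoms(
        coords=np.array(coords),
        radii=np.array(radii),
        residue_uid=np.array(uids, dtype=object),
        is_ca=np.array(is_ca),
        source_id=source_id,
    )
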