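"""Hit tables (TSV/JSON) and aligned pose output (PDB).

Hit tables round-trip losslessly: TSV floats are written with repr-17
precision, JSON uses Python's shortest-round-trip float encoding.  The
stored rigid transform is validated on read — a non-orthogonal rotation
matrix is rejected, since it cannot have come from a least-squares
superposition.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .search import PairHit
from .structures import StructureAtoms

__all__ = ["hits_to_frame", "write_hits_tsv", "read_hits_tsv",
           "write_hits_json", "read_hits_json", "write_pose_pdb"]

_COLUMNS = [
    "subject_source_id", "i", "j", "patch_i", "patch_j",
    "r1", "r2", "r_avg", "distance", "clique_rmsd", "pair_score",
]
_TRANSFORM_COLS = ([f"rot_{r}{c}" for r in range(3) for c in range(3)]
                   + [f"trans_{c}" for c in range(3)])


def hits_to_frame(hits: Sequence[PairHit], w_r: float = 3.0,
                  w_rmsd: float = 1.0) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "subject_source_id": h.subject_source_id,
            "i": h.i, "j": h.j, "patch_i": h.patch_i, "patch_j": h.patch_j,
            "r1": h.r1, "r2": h.r2, "r_avg": h.r_avg,
            "distance": h.distance, "clique_rmsd": h.clique_rmsd,
            "pair_score": h.pair_score(w_r, w_rmsd),
        }
        row.update(dict(zip(_TRANSFORM_COLS,
                            np.concatenate([h.rotation.ravel(), h.translation]))))
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS + _TRANSFORM_COLS)


def _hit_from_row(row: pd.Series, line_no: int) -> PairHit:
    rotation = np.array([row[f"rot_{r}{c}"] for r in range(3) for c in range(3)],
                        dtype=float).reshape(3, 3)
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6):
        raise ValueError(f"line {line_no}: rotation matrix is not orthogonal")
    return PairHit(
        subject_source_id=str(row["subject_source_id"]),
        i=int(row["i"]), j=int(row["j"]),
        patch_i=int(row["patch_i"]), patch_j=int(row["patch_j"]),
        r1=float(row["r1"]), r2=float(row["r2"]),
        distance=float(row["distance"]), clique_rmsd=float(row["clique_rmsd"]),
        rotation=rotation,
        translation=np.array([row[f"trans_{c}"] for c in range(3)], dtype=float),
    )


def write_hits_tsv(hits: Sequence[PairHit], path: str | Path,
                   w_r: float = 3.0, w_rmsd: float = 1.0) -> None:
    hits_to_frame(hits, w_r, w_rmsd).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


def read_hits_tsv(path: str | Path) -> list[PairHit]:
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse hit table ({exc})") from exc
    missing = set(_COLUMNS + _TRANSFORM_COLS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: line 1: missing columns {sorted(missing)}")
    return [_hit_from_row(row, line_no=idx + 2) for idx, row in frame.iterrows()]


def write_hits_json(hits: Sequence[PairHit], path: str | Path,
                    w_r: float = 3.0, w_rmsd: float = 1.0) -> None:
    records = hits_to_frame(hits, w_r, w_rmsd).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))


def read_hits_json(path: str | Path) -> list[PairHit]:
    records = json.loads(Path(path).read_text())
    out = []
    for idx, rec in enumerate(records):
        out.append(_hit_from_row(pd.Series(rec), line_no=idx + 1))
    return out


def write_pose_pdb(
    structure_path: str | Path,
    hit: PairHit,
    out_path: str | Path,
    w_r: float = 3.0,
    w_rmsd: float = 1.0,
) -> None:
    """Write the subject structure transformed into the query frame.

    The hit's rigid transform is applied to every atom; REMARK lines
    record the scores so a pose file is self-describing.
    """
    structure = gemmi.read_structure(str(structure_path))
    transform = gemmi.Transform()
    transform.mat.fromlist(hit.rotation.tolist())
    transform.vec.fromlist(hit.translation.tolist())
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atom.pos = gemmi.Position(*transform.apply(atom.pos).tolist())
    remarks = [
        f"REMARK 250 HECTOR PAIR HIT {hit.subject_source_id} "
        f"PATCHES {hit.patch_i} {hit.patch_j}",
        f"REMARK 250 R1 {hit.r1:.6f} R2 {hit.r2:.6f} RAVG {hit.r_avg:.6f}",
        f"REMARK 250 CLIQUE RMSD {hit.clique_rmsd:.6f} "
        f"PAIR SCORE {hit.pair_score(w_r, w_rmsd):.6f}",
    ]
    body = structure.make_pdb_string()
    Path(out_path).write_text("\n".join(remarks) + "\n" + body)
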