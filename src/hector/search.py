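"""Tiered two-vs-all complementarity search.

Given a pair of inverse query fingerprints separated by a known distance
``d_q``, the search scans a forward-map database for subject patch pairs
that (i) individually score well against the queries, (ii) reproduce the
query spacing, and (iii) superpose onto the query geometry with low
RMSD.  The funnel:

1. candidate selection — the lowest-R subject maps per query (top
   fraction of the whole database, or a fixed count);
2. pair assembly — same-structure candidate pairs whose inter-patch
   distance matches ``d_q`` within a tolerance;
3. average R-factor cutoff;
4. clique alignment — Kabsch superposition of the 4-point clique
   {two patch centers, two normal endpoints} onto the query clique,
   with an RMSD cutoff;
5. ranking by the pair score  3 * R_avg + RMSD  (ascending; R_avg is
   negative for complementary pairs, so strong pairs sort first);
6. optional structural filters on the aligned subject structure —
   occupancy-grid steric clash count and interfacial residue count.

A sequential band-search variant (first-generation protocol) takes the
lowest-N subjects for the first query and pairs each with every
same-structure subject inside the distance band, scoring the second
query only on those.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .db import FingerprintSet
from .fingerprint import Fingerprint
from .rfactor import RFactorConfig, batch_rfactor
from .structures import StructureAtoms

__all__ = [
    "SearchConfig",
    "PairHit",
    "CliqueAlignment",
    "ClashReport",
    "kabsch",
    "select_candidates",
    "assemble_pairs",
    "clique_align",
    "rank_pairs",
    "clash_and_interface_filter",
    "two_vs_all_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the search funnel (defaults follow the second-generation
    protocol: top 5% selection, ±0.01 Å distance band, R_avg < -0.82,
    clique RMSD < 0.5 Å, pair score 3*R_avg + 1*RMSD)."""

    selection_mode: str = "top_fraction"       # or "top_count"
    top_fraction: float = 0.05
    top_count: int = 50
    distance_tolerance: float = 0.01           # Å
    r_avg_cutoff: float | None = -0.82
    clique_rmsd_cutoff: float | None = 0.5     # Å
    normal_length: float | str = 1.0           # Å, or "spacing" => d_q / 2
    w_r: float = 3.0
    w_rmsd: float = 1.0
    min_interface_residues: int = 25
    interface_distance: float = 8.0            # Å, CA-to-any-target-atom
    clash_voxel_size: float = 1.0              # Å
    clash_voxel_cutoff: int = 20               # doubly-occupied voxels
    per_structure_selection: bool = False
    rfactor: RFactorConfig = field(default_factory=RFactorConfig)

    def __post_init__(self) -> None:
        if self.selection_mode not in ("top_fraction", "top_count"):
            raise ValueError("selection_mode must be 'top_fraction' or 'top_count'")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.distance_tolerance < 0:
            raise ValueError("distance_tolerance must be >= 0")
        if isinstance(self.normal_length, str) and self.normal_length != "spacing":
            raise ValueError("normal_length must be a float or 'spacing'")


@dataclass
class CliqueAlignment:
    """Rigid transform (x -> R x + t) and RMSD of a 4-point superposition."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False


@dataclass
class PairHit:
    """One candidate subject patch pair, scored and aligned."""

    subject_source_id: str
    i: int                         # database row of the first subject patch
    j: int                         # database row of the second subject patch
    patch_i: int                   # patch (dot) index on the subject surface
    patch_j: int
    r1: float
    r2: float
    distance: float                # subject inter-patch distance, Å
    clique_rmsd: float
    rotation: np.ndarray           # maps subject coordinates into the query frame
    translation: np.ndarray
    degenerate: bool = False
    clash_voxels: int | None = None
    interface_residues: int | None = None

    @property
    def r_avg(self) -> float:
        return 0.5 * (self.r1 + self.r2)

    def pair_score(self, w_r: float = 3.0, w_rmsd: float = 1.0) -> float:
        return w_r * self.r_avg + w_rmsd * self.clique_rmsd


# ---------------------------------------------------------------------------
# candidate selection and pair assembly


def _selection_order(scores: np.ndarray, db: FingerprintSet) -> np.ndarray:
    """Indices sorted by (score, source id, patch index) — deterministic."""
    return np.lexsort((db.patch_indices, db.source_labels(), scores))


def select_candidates(
    query: Fingerprint | np.ndarray,
    db: FingerprintSet,
    config: SearchConfig,
    scores: np.ndarray | None = None,
) -> np.ndarray:
    """Lowest-R subject map indices for one query.

    In ``top_fraction`` mode exactly ``ceil(fraction * |db|)`` indices
    are returned (the published protocol takes the top 5% of the whole
    multi-structure database); in ``top_count`` mode ``min(count, |db|)``.
    Ties are broken by (R, source id, patch index) so the result is
    reproducible across runs and platforms.  Precomputed ``scores``
    short-circuit the R-factor evaluation.
    """
    if len(db) == 0:
        raise ValueError("cannot select candidates from an empty database")
    if scores is None:
        scores = batch_rfactor(query, db.matrices, config.rfactor)
    if config.selection_mode == "top_fraction":
        n_sel = math.ceil(config.top_fraction * len(db))
    else:
        n_sel = min(config.top_count, len(db))
    return _selection_order(np.asarray(scores, dtype=float), db)[:n_sel]


def assemble_pairs(
    cands1: np.ndarray,
    cands2: np.ndarray,
    d_query: float,
    tol: float,
    db: FingerprintSet,
) -> np.ndarray:
    """Same-structure candidate pairs matching the query spacing.

    Returns an (m, 2) array of database row pairs (i from ``cands1``,
    j from ``cands2``, i != j) with | ||c_i - c_j|| - d_query | <= tol.
    Cross-structure pairs are excluded — a subject pair must come from
    one scaffold to be a docking candidate.
    """
    cands1 = np.asarray(cands1, dtype=np.int64)
    cands2 = np.asarray(cands2, dtype=np.int64)
    if cands1.size == 0 or cands2.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    labels = db.source_labels()
    same = labels[cands1][:, None] == labels[cands2][None, :]
    diff = db.centers[cands1][:, None, :] - db.centers[cands2][None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    ok = same & (np.abs(dist - d_query) <= tol) & (cands1[:, None] != cands2[None, :])
    ii, jj = np.nonzero(ok)
    return np.column_stack([cands1[ii], cands2[jj]])


# ---------------------------------------------------------------------------
# clique alignment


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping points P onto Q.

    Proper rotation only (det = +1): a reflection in the SVD solution is
    corrected by flipping the smallest singular direction.
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def _clique(c1, n1, c2, n2, L: float) -> np.ndarray:
    return np.vstack([c1, c2, c1 + L * np.asarray(n1), c2 + L * np.asarray(n2)])


def clique_align(
    query_pair: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    subject_pair: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    normal_length: float = 1.0,
) -> CliqueAlignment:
    """Superpose a subject patch pair onto a query patch pair.

    Each side contributes a 4-point clique: the two patch centers and
    the endpoints of their normals, scaled to ``normal_length`` Å.  The
    length rescales the weight of patch orientation relative to patch
    spacing in the RMSD; "spacing" normalization (L = d_q/2) is applied
    by the caller.  Returns the proper rotation and translation taking
    subject coordinates into the query frame, and the 4-point RMSD.

    A rank-deficient (collinear) clique is flagged ``degenerate``; the
    RMSD is still returned but the rotation about the degenerate axis is
    arbitrary.
    """
    qc1, qn1, qc2, qn2 = (np.asarray(v, dtype=float) for v in query_pair)
    sc1, sn1, sc2, sn2 = (np.asarray(v, dtype=float) for v in subject_pair)
    Q = _clique(qc1, qn1, qc2, qn2, normal_length)
    S = _clique(sc1, sn1, sc2, sn2, normal_length)
    R, t = kabsch(S, Q)
    sv = np.linalg.svd(S - S.mean(axis=0), compute_uv=False)
    degenerate = bool(sv[1] < 1e-9 * max(sv[0], 1.0))
    resid = S @ R.T + t - Q
    rmsd = float(np.sqrt(np.einsum("ij,ij->", resid, resid) / len(Q)))
    return CliqueAlignment(rotation=R, translation=t, rmsd=rmsd, degenerate=degenerate)


# ---------------------------------------------------------------------------
# ranking and structural filters


def rank_pairs(pairs: Sequence[PairHit], config: SearchConfig,
               apply_filters: bool = True) -> list[PairHit]:
    """Filter by the R_avg / RMSD cutoffs and sort by pair score.

    Ordering is ascending in ``w_r * R_avg + w_rmsd * RMSD`` with
    deterministic (source id, i, j) tie-breaking.  Cutoffs set to
    ``None`` (or ``apply_filters=False``) disable filtering.
    """
    kept = []
    for hit in pairs:
        if apply_filters:
            if config.r_avg_cutoff is not None and not hit.r_avg < config.r_avg_cutoff:
                continue
            if (config.clique_rmsd_cutoff is not None
                    and not hit.clique_rmsd < config.clique_rmsd_cutoff):
                continue
        kept.append(hit)
    return sorted(kept, key=lambda h: (h.pair_score(config.w_r, config.w_rmsd),
                                       h.subject_source_id, h.i, h.j))


@dataclass
class ClashReport:
    clash_voxels: int
    overlap_volume: float          # Å^3
    interface_residues: int
    passed: bool


def _occupied_voxels(atoms: StructureAtoms, origin: np.ndarray, shape: np.ndarray,
                     voxel: float) -> np.ndarray:
    """Boolean occupancy grid: voxels whose center lies inside any atom."""
    occ = np.zeros(shape, dtype=bool)
    axes = [origin[d] + voxel * (np.arange(shape[d]) + 0.5) for d in range(3)]
    for pos, r in zip(atoms.coords, atoms.radii):
        lo = np.maximum(((pos - r - origin) / voxel).astype(int), 0)
        hi = np.minimum(((pos + r - origin) / voxel).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        dx = axes[0][lo[0]:hi[0]] - pos[0]
        dy = axes[1][lo[1]:hi[1]] - pos[1]
        dz = axes[2][lo[2]:hi[2]] - pos[2]
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return occ


def clash_and_interface_filter(
    subject: StructureAtoms,
    target: StructureAtoms,
    config: SearchConfig,
) -> ClashReport:
    """Steric-clash and interface-size check for an aligned pose.

    Both structures are rasterized onto a shared occupancy grid at
    ``clash_voxel_size`` (voxel centers inside any van der Waals sphere
    count as occupied); the clash measure is the number of doubly
    occupied voxels, also reported as an overlap volume in Å^3.
    Interfacial residues are subject residues whose CA lies within
    ``interface_distance`` (default 8 Å) of any target atom.  The pose
    passes if the clash count stays below the cutoff and the interface
    is at least ``min_interface_residues`` residues.
    """
    if len(subject) == 0 or len(target) == 0:
        raise ValueError("clash filter requires non-empty structures")
    voxel = config.clash_voxel_size
    rmax = max(subject.radii.max(), target.radii.max())
    lo = np.minimum(subject.coords.min(axis=0), target.coords.min(axis=0)) - rmax - voxel
    hi = np.maximum(subject.coords.max(axis=0), target.coords.max(axis=0)) + rmax + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int)
    occ_s = _occupied_voxels(subject, lo, shape, voxel)
    occ_t = _occupied_voxels(target, lo, shape, voxel)
    clash = int(np.count_nonzero(occ_s & occ_t))

    ca = subject.coords[subject.is_ca]
    ca_uid = subject.residue_uid[subject.is_ca]
    if len(ca):
        tree = cKDTree(target.coords)
        near = tree.query_ball_point(ca, r=config.interface_distance)
        n_interface = len({uid for uid, hits in zip(ca_uid, near) if hits})
    else:
        n_interface = 0
    passed = clash < config.clash_voxel_cutoff and n_interface >= config.min_interface_residues
    return ClashReport(
        clash_voxels=clash,
        overlap_volume=clash * voxel**3,
        interface_residues=n_interface,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# orchestration


def _query_geometry(q1: Fingerprint, q2: Fingerprint) -> tuple[float, tuple]:
    d_q = float(np.linalg.norm(q1.center - q2.center))
    return d_q, (q1.center, q1.normal, q2.center, q2.normal)


def two_vs_all_search(
    q1: Fingerprint,
    q2: Fingerprint,
    db: FingerprintSet,
    config: SearchConfig | None = None,
    scores1: np.ndarray | None = None,
    scores2: np.ndarray | None = None,
    mode: str = "symmetric",
    apply_filters: bool = True,
    align: bool = True,
    subject_structures: Mapping[str, StructureAtoms] | None = None,
    target_structure: StructureAtoms | None = None,
) -> list[PairHit]:
    """Run the full search funnel for one query patch pair.

    ``mode='symmetric'`` is the two-sided protocol: candidates are
    selected independently for both queries and paired under the
    distance constraint.  ``mode='sequential'`` is the first-generation
    band search: the lowest-``top_count`` subjects for the first query
    are each paired with every same-structure subject inside the
    distance band, and the second query is scored on those.

    ``scores1``/``scores2`` accept precomputed R-factor rows (queries
    vs. the whole database) so a caller scoring many query pairs against
    one database pays for the batch evaluation once.

    When ``subject_structures`` and ``target_structure`` are provided,
    each surviving hit is additionally screened by the clash/interface
    filter in its aligned pose, and the hit records the counts.

    ``align=False`` skips the clique alignment (hits carry an identity
    transform and zero RMSD); only meaningful when downstream consumers
    ignore pose and RMSD, e.g. random-ranking null models.
    """
    config = config or SearchConfig()
    if len(db) == 0:
        return []
    if scores1 is None:
        scores1 = batch_rfactor(q1, db.matrices, config.rfactor)
    if scores2 is None:
        scores2 = batch_rfactor(q2, db.matrices, config.rfactor)
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    d_q, query_geo = _query_geometry(q1, q2)

    if mode == "symmetric":
        if config.per_structure_selection:
            labels = db.source_labels()
            cands1 = np.concatenate([
                _per_label_select(scores1, db, config, labels, lab)
                for lab in np.unique(labels)
            ])
            cands2 = np.concatenate([
                _per_label_select(scores2, db, config, labels, lab)
                for lab in np.unique(labels)
            ])
        else:
            cands1 = select_candidates(q1, db, config, scores=scores1)
            cands2 = select_candidates(q2, db, config, scores=scores2)
        pairs = assemble_pairs(cands1, cands2, d_q, config.distance_tolerance, db)
    elif mode == "sequential":
        seq_cfg = replace(config, selection_mode="top_count")
        cands1 = select_candidates(q1, db, seq_cfg, scores=scores1)
        pairs = assemble_pairs(cands1, np.arange(len(db)), d_q,
                               config.distance_tolerance, db)
    else:
        raise ValueError("mode must be 'symmetric' or 'sequential'")

    L = 0.5 * d_q if config.normal_length == "spacing" else float(config.normal_length)
    hits: list[PairHit] = []
    for i, j in pairs:
        r_avg = 0.5 * (scores1[i] + scores2[j])
        if (apply_filters and config.r_avg_cutoff is not None
                and not r_avg < config.r_avg_cutoff):
            continue
        if align:
            alignment = clique_align(
                query_geo,
                (db.centers[i], db.normals[i], db.centers[j], db.normals[j]),
                normal_length=L,
            )
        else:
            alignment = CliqueAlignment(np.eye(3), np.zeros(3), 0.0)
        hits.append(PairHit(
            subject_source_id=str(db.source_ids[i]),
            i=int(i), j=int(j),
            patch_i=int(db.patch_indices[i]), patch_j=int(db.patch_indices[j]),
            r1=float(scores1[i]), r2=float(scores2[j]),
            distance=float(np.linalg.norm(db.centers[i] - db.centers[j])),
            clique_rmsd=alignment.rmsd,
            rotation=alignment.rotation, translation=alignment.translation,
            degenerate=alignment.degenerate,
        ))
    ranked = rank_pairs(hits, config, apply_filters=apply_filters)

    if subject_structures is not None and target_structure is not None:
        screened = []
        for hit in ranked:
            atoms = subject_structures[hit.subject_source_id]
            report = clash_and_interface_filter(
                atoms.transformed(hit.rotation, hit.translation),
                target_structure, config,
            )
            hit.clash_voxels = report.clash_voxels
            hit.interface_residues = report.interface_residues
            if report.passed or not apply_filters:
                screened.append(hit)
        ranked = screened
    return ranked


def _per_label_select(scores, db, config, labels, lab) -> np.ndarray:
    sub = np.flatnonzero(labels == lab)
    order = np.lexsort((db.patch_indices[sub], sub, scores[sub]))
    if config.selection_mode == "top_fraction":
        n_sel = math.ceil(config.top_fraction * len(sub))
    else:
        n_sel = min(config.top_count, len(sub))
    return sub[order[:n_sel]]
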