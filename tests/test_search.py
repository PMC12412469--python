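"""Candidate selection, pair assembly, clique alignment, ranking, filters."""

import math
from dataclasses import replace

import numpy as np
import pytest

from hector import (
    Fingerprint,
    MapParams,
    PairHit,
    SearchConfig,
    assemble_pairs,
    clash_and_interface_filter,
    clique_align,
    rank_pairs,
    rfactor_v02,
    select_candidates,
    two_vs_all_search,
)
from hector.rfactor import batch_rfactor
from hector.search import kabsch
from hector.structures import synthetic_helix

from conftest import horn_align, toy_fingerprint_set

SMALL = MapParams(r_max=3.0, h_max=4.0, resolution=0.5)   # 6 x 8 maps


def _query_from(db, idx, center=None, normal=None):
    return Fingerprint(
        matrix=db.matrices[idx].astype(np.float64), k=-1,
        center=db.centers[idx] if center is None else np.asarray(center, float),
        normal=db.normals[idx] if normal is None else np.asarray(normal, float),
        source_id="query", patch_index=int(idx),
    )


class TestSelectCandidates:
    def test_top_fraction_matches_sort_oracle(self, rng):
        db = toy_fingerprint_set(rng, 100, SMALL)
        q = _query_from(db, 0)
        scores = batch_rfactor(q.matrix, db.matrices)
        got = select_candidates(q, db, SearchConfig())
        assert len(got) == 5
        oracle = sorted(range(100), key=lambda i: (scores[i], str(db.source_ids[i]),
                                                   db.patch_indices[i]))[:5]
        assert list(got) == oracle

    def test_exact_complement_always_selected(self, rng):
        db = toy_fingerprint_set(rng, 200, SMALL)
        q = _query_from(db, 17)         # db row 17 equals the query map
        got = select_candidates(q, db, SearchConfig())
        assert 17 in got

    def test_top_count_clamps(self, rng):
        db = toy_fingerprint_set(rng, 30, SMALL)
        cfg = SearchConfig(selection_mode="top_count", top_count=50)
        assert len(select_candidates(_query_from(db, 0), db, cfg)) == 30

    def test_tie_break_deterministic(self, rng):
        db = toy_fingerprint_set(rng, 20, SMALL)
        db.matrices[:] = db.matrices[0]          # all scores tie
        got = select_candidates(_query_from(db, 0), db, SearchConfig(top_fraction=0.25))
        assert list(got) == [0, 1, 2, 3, 4]


class TestAssemblePairs:
    def test_no_filter_counts(self, rng):
        db = toy_fingerprint_set(rng, 12, SMALL)
        c1, c2 = np.arange(4), np.arange(2, 8)
        pairs = assemble_pairs(c1, c2, d_query=5.0, tol=np.inf, db=db)
        expect = sum(1 for i in c1 for j in c2 if i != j)
        assert len(pairs) == expect

    def test_single_consistent_pair(self, rng):
        db = toy_fingerprint_set(rng, 10, SMALL)
        db.centers[3] = [0.0, 0.0, 0.0]
        db.centers[7] = [6.0, 0.0, 0.0]
        pairs = assemble_pairs(np.array([3]), np.array([7, 8]), d_query=6.0,
                               tol=0.01, db=db)
        # random centers are generic: only the planted pair hits 6 ± 0.01
        assert pairs.tolist() == [[3, 7]]

    def test_zero_tolerance_no_match(self, rng):
        db = toy_fingerprint_set(rng, 10, SMALL)
        pairs = assemble_pairs(np.arange(5), np.arange(5, 10), d_query=1.2345,
                               tol=0.0, db=db)
        assert len(pairs) == 0

    def test_cross_structure_pairs_excluded(self, rng):
        db = toy_fingerprint_set(rng, 10, SMALL, n_sources=2)
        pairs = assemble_pairs(np.arange(10), np.arange(10), d_query=5.0,
                               tol=np.inf, db=db)
        labels = db.source_labels()
        assert all(labels[i] == labels[j] for i, j in pairs)


def _random_clique_pair(rng):
    q = rng.normal(scale=5.0, size=(4, 3))
    s = rng.normal(scale=5.0, size=(4, 3))
    return q, s


class TestCliqueAlign:
    def _geo(self, c1, n1, c2, n2):
        return (np.asarray(c1, float), np.asarray(n1, float),
                np.asarray(c2, float), np.asarray(n2, float))

    def test_identity(self):
        geo = self._geo([0, 0, 0], [0, 0, 1], [5, 0, 0], [0, 1, 0])
        out = clique_align(geo, geo)
        assert np.allclose(out.rotation, np.eye(3), atol=1e-12)
        assert out.rmsd < 1e-12

    def test_recovers_planted_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        geo = self._geo([1, 2, 3], [0, 0, 1], [6, 2, 3], [0, 1, 0])
        R0 = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        t0 = rng.normal(scale=10.0, size=3)
        subject = self._geo(R0 @ geo[0] + t0, R0 @ geo[1],
                            R0 @ geo[2] + t0, R0 @ geo[3])
        out = clique_align(geo, subject)
        # the recovered transform undoes the planted one
        assert np.allclose(out.rotation, R0.T, atol=1e-6)
        assert out.rmsd < 1e-6

    def test_matches_horn_oracle(self, rng):
        for _ in range(1000):
            Q, S = _random_clique_pair(rng)
            R, t = kabsch(S, Q)
            resid = S @ R.T + t - Q
            rmsd = np.sqrt((resid**2).sum() / 4)
            _, _, rmsd_horn = horn_align(S, Q)
            assert abs(rmsd - rmsd_horn) < 1e-6

    def test_degenerate_collinear_flagged(self):
        # all four points on the x-axis
        geo = self._geo([0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 0, 0])
        out = clique_align(geo, geo)
        assert out.degenerate
        assert out.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_normal_length_scales_orientation_residual(self):
        from scipy.spatial.transform import Rotation

        # centers agree; subject normals tilted about the inter-center
        # axis, so center residuals stay zero and the endpoint residual
        # is purely orientational -> RMSD is linear in normal length
        c1, c2 = np.zeros(3), np.array([4.0, 0, 0])
        n1 = n2 = np.array([0.0, 0.0, 1.0])
        tilt = Rotation.from_rotvec([0.3, 0.0, 0.0]).as_matrix()
        query = (c1, n1, c2, n2)
        subject = (c1, tilt @ n1, c2, tilt @ n2)
        r1 = clique_align(query, subject, normal_length=1.0).rmsd
        r2 = clique_align(query, subject, normal_length=2.0).rmsd
        assert r2 == pytest.approx(2.0 * r1, rel=1e-9)


class TestRankPairs:
    def _hit(self, r_avg, rmsd, src="s0", i=0, j=1):
        return PairHit(subject_source_id=src, i=i, j=j, patch_i=i, patch_j=j,
                       r1=r_avg, r2=r_avg, distance=1.0, clique_rmsd=rmsd,
                       rotation=np.eye(3), translation=np.zeros(3))

    def test_score_arithmetic(self):
        assert self._hit(-1.0, 0.0).pair_score() == pytest.approx(-3.0)

    def test_tie_breaking(self):
        a = self._hit(-0.9, 0.1, src="s1", i=5, j=6)
        b = self._hit(-0.9, 0.1, src="s0", i=2, j=3)
        cfg = SearchConfig(r_avg_cutoff=None, clique_rmsd_cutoff=None)
        assert rank_pairs([a, b], cfg) == [b, a]

    def test_filters_match_brute_force(self, rng):
        hits = [self._hit(rng.uniform(-1.0, 0.0), rng.uniform(0.0, 1.0), i=i, j=i + 1)
                for i in range(200)]
        cfg = SearchConfig()
        survivors = rank_pairs(hits, cfg)
        oracle = {(h.i, h.j) for h in hits
                  if h.r_avg < -0.82 and h.clique_rmsd < 0.5}
        assert {(h.i, h.j) for h in survivors} == oracle

    def test_score_monotonicity(self):
        cfg = SearchConfig(r_avg_cutoff=None, clique_rmsd_cutoff=None)
        base = self._hit(-0.9, 0.2, i=0, j=1)
        better_r = self._hit(-0.95, 0.2, i=2, j=3)
        better_rmsd = self._hit(-0.9, 0.1, i=4, j=5)
        ranked = rank_pairs([base, better_r, better_rmsd], cfg)
        assert ranked.index(better_r) < ranked.index(base)
        assert ranked.index(better_rmsd) < ranked.index(base)


class TestClashInterface:
    def test_full_self_overlap(self):
        helix = synthetic_helix(10)
        cfg = SearchConfig(clash_voxel_size=1.0)
        report = clash_and_interface_filter(helix, helix, cfg)
        # identical structures doubly occupy exactly their own voxel set
        from hector.search import _occupied_voxels

        rmax = helix.radii.max()
        lo = helix.coords.min(axis=0) - rmax - 1.0
        hi = helix.coords.max(axis=0) + rmax + 1.0
        shape = np.ceil((hi - lo) / 1.0).astype(int)
        own = int(_occupied_voxels(helix, lo, shape, 1.0).sum())
        assert report.clash_voxels == own
        assert not report.passed

    def test_distant_structures(self):
        a = synthetic_helix(30)
        b = synthetic_helix(30, offset=np.array([100.0, 0.0, 0.0]))
        report = clash_and_interface_filter(a, b, SearchConfig())
        assert report.clash_voxels == 0
        assert report.interface_residues == 0
        assert not report.passed

    def test_interface_count_matches_hand_enumeration(self):
        a = synthetic_helix(30)
        b = synthetic_helix(30, offset=np.array([9.0, 0.0, 0.0]))
        cfg = SearchConfig(min_interface_residues=5)
        report = clash_and_interface_filter(a, b, cfg)
        ca = a.coords[a.is_ca]
        dmat = np.linalg.norm(ca[:, None, :] - b.coords[None, :, :], axis=2)
        expected = int((dmat.min(axis=1) <= cfg.interface_distance).sum())
        assert report.interface_residues == expected

    def test_interpenetration_fails(self):
        a = synthetic_helix(30)
        b = synthetic_helix(30, offset=np.array([5.0, 0.0, 0.0]))
        report = clash_and_interface_filter(a, b, SearchConfig())
        assert report.clash_voxels >= SearchConfig().clash_voxel_cutoff
        assert not report.passed

    def test_empty_structure_rejected(self):
        import dataclasses

        helix = synthetic_helix(5)
        empty = dataclasses.replace(
            helix, coords=np.empty((0, 3)), radii=np.empty(0),
            residue_uid=np.empty(0, object), is_ca=np.empty(0, bool))
        with pytest.raises(ValueError):
            clash_and_interface_filter(empty, helix, SearchConfig())


def _planted_db(rng, n=400, d=7.0):
    """Random db with one planted exactly-complementary, geometry-true pair."""
    db = toy_fingerprint_set(rng, n, SMALL, n_sources=4)
    q_center1 = np.array([50.0, 0.0, 0.0])
    q_center2 = np.array([50.0 + d, 0.0, 0.0])
    q_normal = np.array([0.0, 0.0, 1.0])
    i0, j0 = 40, 44                               # same source: 40 % 4 == 44 % 4
    db.centers[i0], db.centers[j0] = [0.0, 0, 0], [d, 0, 0]
    db.normals[i0] = db.normals[j0] = q_normal
    q1 = Fingerprint(matrix=db.matrices[i0].astype(np.float64), k=-1,
                     center=q_center1, normal=q_normal, source_id="q", patch_index=0)
    q2 = Fingerprint(matrix=db.matrices[j0].astype(np.float64), k=-1,
                     center=q_center2, normal=q_normal, source_id="q", patch_index=1)
    return db, q1, q2, (i0, j0)


class TestTwoVsAll:
    def test_planted_complement_ranks_first(self, rng):
        db, q1, q2, planted = _planted_db(rng)
        hits = two_vs_all_search(q1, q2, db, SearchConfig())
        assert hits, "planted pair must survive all filters"
        assert (hits[0].i, hits[0].j) == planted
        assert hits[0].r_avg == -1.0
        assert hits[0].clique_rmsd < 1e-9

    def test_deterministic_hit_table(self, rng):
        from hector.tables import hits_to_frame

        db, q1, q2, _ = _planted_db(rng)
        cfg = SearchConfig(r_avg_cutoff=None, clique_rmsd_cutoff=None,
                           distance_tolerance=2.0)
        t1 = hits_to_frame(two_vs_all_search(q1, q2, db, cfg)).to_csv()
        t2 = hits_to_frame(two_vs_all_search(q1, q2, db, cfg)).to_csv()
        assert t1 == t2

    def test_sequential_band_search(self, rng):
        db, q1, q2, planted = _planted_db(rng)
        cfg = SearchConfig(selection_mode="top_count", top_count=50,
                           distance_tolerance=3.0, r_avg_cutoff=None,
                           clique_rmsd_cutoff=None)
        hits = two_vs_all_search(q1, q2, db, cfg, mode="sequential")
        assert (hits[0].i, hits[0].j) == planted
        top = select_candidates(q1, db, cfg)
        d_q = np.linalg.norm(q1.center - q2.center)
        for h in hits:
            assert h.i in top
            assert abs(h.distance - d_q) <= cfg.distance_tolerance

    def test_pipeline_equals_brute_force_funnel(self, rng):
        db = toy_fingerprint_set(rng, 500, SMALL, n_sources=5, spread=20.0)
        q1 = _query_from(db, 3, center=[0, 0, 0], normal=[0, 0, 1])
        q2 = _query_from(db, 4, center=[6, 0, 0], normal=[0, 1, 0])
        cfg = SearchConfig(distance_tolerance=2.0, r_avg_cutoff=-0.5,
                           clique_rmsd_cutoff=4.0)
        hits = two_vs_all_search(q1, q2, db, cfg)

        # independent exhaustive enumeration of the same four filters
        scores1 = np.array([rfactor_v02(db.matrices[i], q1.matrix)
                            for i in range(500)])
        scores2 = np.array([rfactor_v02(db.matrices[i], q2.matrix)
                            for i in range(500)])
        n_sel = math.ceil(0.05 * 500)
        key1 = sorted(range(500), key=lambda i: (scores1[i], str(db.source_ids[i]),
                                                 db.patch_indices[i]))[:n_sel]
        key2 = sorted(range(500), key=lambda i: (scores2[i], str(db.source_ids[i]),
                                                 db.patch_indices[i]))[:n_sel]
        d_q = np.linalg.norm(q1.center - q2.center)
        survivors = set()
        for i in key1:
            for j in key2:
                if i == j or db.source_ids[i] != db.source_ids[j]:
                    continue
                if abs(np.linalg.norm(db.centers[i] - db.centers[j]) - d_q) > 2.0:
                    continue
                if not (scores1[i] + scores2[j]) / 2 < -0.5:
                    continue
                Q = np.vstack([q1.center, q2.center, q1.center + q1.normal,
                               q2.center + q2.normal])
                S = np.vstack([db.centers[i], db.centers[j],
                               db.centers[i] + db.normals[i],
                               db.centers[j] + db.normals[j]])
                _, _, rmsd = horn_align(S, Q)
                if rmsd < 4.0:
                    survivors.add((i, j))
        assert {(h.i, h.j) for h in hits} == survivors
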