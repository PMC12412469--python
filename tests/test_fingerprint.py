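"""Patch extraction, cylindrical projection, binning, and map invariances."""

import numpy as np
import pytest

from hector import (
    FORWARD,
    INVERSE,
    V01,
    V02,
    MapParams,
    bilinear_smooth,
    extract_patch,
    fingerprint_patch,
    fingerprint_surface,
    inflate_surface,
    make_sphere,
    project_cylindrical,
    rasterize,
    rfactor_v02,
)
from hector.fingerprint import fade_weights, _orthonormal_completion

from conftest import make_plane

COARSE = MapParams(r_max=4.0, h_max=8.0, resolution=0.5, map_frequency=5)


class TestMapParams:
    def test_preset_map_dimensions(self):
        assert V02.shape == (50, 100)
        assert V01.shape == (30, 30)

    def test_non_integer_span_rejected(self):
        with pytest.raises(ValueError):
            MapParams(r_max=10.0, h_max=20.0, resolution=0.3)

    def test_hash_distinguishes_presets(self):
        assert V01.params_hash() != V02.params_hash()


class TestExtractPatch:
    def test_plane_patch_is_disc(self):
        plane = make_plane(spacing=0.5, half_extent=15.0)
        center = np.argmin(np.linalg.norm(plane.points, axis=1))
        patch = extract_patch(plane, int(center), V02)
        r = np.hypot(patch.local_dots[:, 0], patch.local_dots[:, 1])
        assert np.all(r < V02.r_max)
        assert np.abs(patch.local_dots[:, 2]).max() < 1e-9
        # the grid fills the disc: count close to pi r^2 / spacing^2
        assert len(patch) == pytest.approx(np.pi * V02.r_max**2 / 0.25, rel=0.02)

    def test_boundary_dot_excluded(self):
        from hector import DotSurface

        pts = np.array([[0.0, 0, 0], [V02.r_max, 0, 0], [V02.r_max - 1e-6, 0, 0]])
        surf = DotSurface(pts, np.tile([0, 0, 1.0], (3, 1)), np.ones(3))
        patch = extract_patch(surf, 0, V02)
        assert len(patch) == 2          # center and the interior dot only

    def test_axial_bounds(self, small_sphere):
        patch = extract_patch(small_sphere, 0, V02)
        assert np.abs(patch.local_dots[:, 2]).max() < V02.h_max / 2

    def test_dot_stride_keeps_every_kth_member(self, small_sphere):
        from dataclasses import replace

        full = extract_patch(small_sphere, 5, replace(V01, dot_stride=1))
        strided = extract_patch(small_sphere, 5, V01)
        assert len(strided) == int(np.ceil(len(full) / V01.dot_stride))

    def test_local_frame_round_trip(self, small_sphere):
        from scipy.spatial import cKDTree

        patch = extract_patch(small_sphere, 3, V02)
        # local coordinates must reproduce the original global positions
        dist, _ = cKDTree(small_sphere.points).query(patch.to_global())
        assert dist.max() < 1e-9


class TestProjection:
    def test_forward_axis_point(self):
        patch = _patch_from_local(np.array([[1.0, 0.0, 2.0]]))
        triples = project_cylindrical(patch, k=FORWARD)
        assert np.allclose(triples[0], [1.0, 0.0, 2.0])

    def test_inverse_flips_axial(self):
        patch = _patch_from_local(np.array([[0.0, 1.0, 2.0]]))
        triples = project_cylindrical(patch, k=INVERSE)
        assert np.allclose(triples[0], [1.0, np.pi / 2, -2.0])

    def test_inverse_equals_mirrored_forward(self, rng):
        local = rng.normal(size=(50, 3))
        inv = project_cylindrical(_patch_from_local(local), k=INVERSE)
        mirrored = local * [1, 1, -1]
        fwd = project_cylindrical(_patch_from_local(mirrored), k=FORWARD)
        assert np.allclose(np.sort(inv, axis=0), np.sort(fwd, axis=0))


def _patch_from_local(local):
    from hector import SurfacePatch

    return SurfacePatch(
        center_index=0, center=np.zeros(3), normal=np.array([0, 0, 1.0]),
        local_dots=np.asarray(local, dtype=float),
        local_weights=np.ones(len(local)), frame=np.eye(3),
    )


class TestRasterize:
    def test_empty_input_gives_zero_map(self):
        fp = rasterize(np.empty((0, 3)), V02)
        assert fp.matrix.shape == (50, 100)
        assert np.all(fp.matrix == 0)

    def test_single_dot_bin_and_fade_value(self):
        fp = rasterize(np.array([[1.0, 0.0, 0.0]]), V02)
        nz = np.nonzero(fp.matrix)
        assert (nz[0][0], nz[1][0]) == (5, 50)
        expected = 1.0 / (1.0 + np.exp(V02.fade_slope * (5 + 0.5 - 40)))
        assert fp.matrix[5, 50] == pytest.approx(expected, rel=1e-12)

    def test_fade_sigmoid_midpoint_is_half(self):
        # continuous sigmoid crosses 1/2 exactly at the fade radius
        w = fade_weights(V02)
        slope, r0 = V02.fade_slope, V02.fade_radius_bins
        assert 1.0 / (1.0 + np.exp(slope * (r0 - r0))) == 0.5
        assert w[r0 - 1] > 0.5 > w[r0]

    def test_out_of_span_dot_asserts(self):
        with pytest.raises(AssertionError):
            rasterize(np.array([[V02.r_max + 1.0, 0.0, 0.0]]), V02)


class TestBilinearSmooth:
    def test_constant_is_fixed_point(self):
        m = np.full((6, 7), 3.25)
        assert np.allclose(bilinear_smooth(m), m, atol=1e-12)

    def test_impulse_mass_preserved_and_local(self):
        m = np.zeros((9, 9))
        m[4, 4] = 2.0
        out = bilinear_smooth(m)
        assert out.sum() == pytest.approx(2.0, rel=1e-12)
        assert np.count_nonzero(out) == 5       # itself + 4 edge neighbours
        assert out[4, 4] == pytest.approx(1.0)

    def test_zero_map_unchanged(self):
        assert np.all(bilinear_smooth(np.zeros((5, 5))) == 0)

    def test_mass_conserved_at_edges(self, rng):
        m = rng.uniform(size=(12, 17))
        assert bilinear_smooth(m).sum() == pytest.approx(m.sum(), rel=1e-9)


class TestFingerprintSurface:
    def test_center_count_arithmetic(self, small_sphere):
        params = MapParams(r_max=4.0, h_max=8.0, resolution=0.5, map_frequency=5)
        n = len(small_sphere)
        fps = fingerprint_surface(small_sphere, params)
        assert len(fps) == int(np.ceil(n / 5))

    def test_maps_per_area_matches_mapping_frequency(self):
        surf = make_sphere(12.0, density=20.0, seed=4)
        fps = fingerprint_surface(surf, V02)
        assert len(fps) / surf.total_area == pytest.approx(4.0, rel=0.02)
        fps40 = fingerprint_surface(surf, V01)
        assert len(fps40) / surf.total_area == pytest.approx(0.5, rel=0.02)

    def test_vectorized_matches_per_patch_route(self, small_sphere):
        for params in (COARSE, V01):
            fast = fingerprint_surface(small_sphere, params, k=INVERSE)
            for fp in fast[::7]:
                patch = extract_patch(small_sphere, fp.patch_index, params)
                slow = fingerprint_patch(patch, params, k=INVERSE)
                assert np.allclose(fp.matrix, slow.matrix, atol=1e-9), params.version_tag


class TestInvariances:
    def _rotated(self, surface, rotation, translation):
        from hector import DotSurface

        return DotSurface(
            surface.points @ rotation.T + translation,
            surface.normals @ rotation.T,
            surface.areas, source_id=surface.source_id,
        )

    def test_rigid_motion_leaves_maps_unchanged(self, small_sphere):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = self._rotated(small_sphere, rot, np.array([11.0, -5.0, 3.0]))
        base = fingerprint_surface(small_sphere, COARSE)
        out = fingerprint_surface(moved, COARSE)
        for f1, f2 in zip(base, out):
            assert np.abs(f1.matrix - f2.matrix).max() < 1e-6

    def test_pure_translation_is_exact(self, small_sphere):
        moved = self._rotated(small_sphere, np.eye(3), np.array([2.0, 4.0, -1.0]))
        base = fingerprint_surface(small_sphere, COARSE)
        out = fingerprint_surface(moved, COARSE)
        for f1, f2 in zip(base, out):
            assert np.array_equal(f1.matrix, f2.matrix)

    def test_local_frame_choice_immaterial(self, small_sphere, rng):
        from scipy.spatial.transform import Rotation

        idx = 11
        patch = extract_patch(small_sphere, idx, COARSE)
        spin = Rotation.from_rotvec([0, 0, rng.uniform(0, 2 * np.pi)]).as_matrix()
        alt_frame = spin @ patch.frame       # same z, rotated x/y completion
        alt = extract_patch(small_sphere, idx, COARSE, frame=alt_frame)
        f1 = fingerprint_patch(patch, COARSE)
        f2 = fingerprint_patch(alt, COARSE)
        assert np.abs(f1.matrix - f2.matrix).max() < 1e-9

    def test_inverse_is_axially_reversed_forward(self, small_sphere):
        fwd = fingerprint_surface(small_sphere, COARSE, k=FORWARD)
        inv = fingerprint_surface(small_sphere, COARSE, k=INVERSE)
        for f, i in zip(fwd, inv):
            assert np.array_equal(i.matrix, f.matrix[:, ::-1])


class TestComplementaritySignal:
    def test_true_complements_score_below_decoys(self, split_pair, rng):
        a, b, corr = split_pair
        ia = inflate_surface(a, V02.inflation)
        ib = inflate_surface(b, V02.inflation)
        sel = corr[rng.choice(len(corr), 4, replace=False)]
        decoy_idx = rng.choice(len(b), 30, replace=False)
        n_better = n_total = 0
        for ka, kb in sel:
            inv_a = fingerprint_patch(extract_patch(ia, int(ka), V02), V02, k=INVERSE)
            fwd_b = fingerprint_patch(extract_patch(ib, int(kb), V02), V02, k=FORWARD)
            r_true = rfactor_v02(fwd_b.matrix, inv_a.matrix)
            assert r_true < -0.8        # certified-core pairs are near-perfect
            for kd in decoy_idx:
                if kd == kb:
                    continue
                fwd_d = fingerprint_patch(extract_patch(ib, int(kd), V02), V02,
                                          k=FORWARD)
                n_better += r_true < rfactor_v02(fwd_d.matrix, inv_a.matrix)
                n_total += 1
        assert n_better / n_total >= 0.9
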