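"""Shared fixtures: small analytic surfaces and structure files.

Everything is generated programmatically; heavier fixtures are
session-scoped so expensive surface builds run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hector import DotSurface, TriMesh, make_sphere, make_split_pair


@pytest.fixture(scope="session")
def octahedron_mesh() -> TriMesh:
    """Unit octahedron: 6 vertices, 8 faces, outward-consistent winding."""
    verts = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], dtype=float)
    faces = np.array([
        [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
        [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
    ])
    return TriMesh(vertices=verts, faces=faces)


@pytest.fixture(scope="session")
def sphere10() -> DotSurface:
    return make_sphere(10.0, density=20.0, seed=1)


@pytest.fixture(scope="session")
def small_sphere() -> DotSurface:
    """Radius-4 sphere at working density: cheap but realistically dense."""
    return make_sphere(4.0, density=20.0, seed=7)


@pytest.fixture(scope="session")
def split_pair():
    """Split solid large enough that core interface patches see only
    complementary surface at the default 10 Å patch span."""
    return make_split_pair(seed=3, size=14.0, roughness=0.6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_plane(spacing: float = 0.25, half_extent: float = 13.0) -> DotSurface:
    """Flat square dot grid in the z = 0 plane with +z normals."""
    ax = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    xv, yv = np.meshgrid(ax, ax)
    pts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(xv.size)])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    areas = np.full(len(pts), spacing**2)
    return DotSurface(pts, normals, areas, source_id="plane")


def toy_fingerprint_set(rng, n, params, n_sources=1, spread=30.0, k=1):
    """Random fingerprint stack with random geometry, for search tests."""
    from hector import FingerprintSet

    br, bl = params.shape
    normals = rng.normal(size=(n, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    sources = np.array([f"s{idx % n_sources}" for idx in range(n)], dtype=object)
    return FingerprintSet(
        matrices=rng.uniform(0.0, 4.0, size=(n, br, bl)).astype(np.float32),
        centers=rng.uniform(-spread / 2, spread / 2, size=(n, 3)),
        normals=normals,
        source_ids=sources,
        patch_indices=np.arange(n),
        k=k, params=params,
    )


def horn_align(P, Q):
    """Independent rigid-superposition oracle (Horn's quaternion method)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    S = (P - pc).T @ (Q - qc)
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = qc - R @ pc
    resid = P @ R.T + t - Q
    return R, t, float(np.sqrt((resid**2).sum() / len(P)))


def write_pdb(path, atoms) -> None:
    """Minimal fixed-width PDB writer for StructureAtoms test fixtures."""
    lines = []
    serial = 1
    for (x, y, z), uid, is_ca in zip(atoms.coords, atoms.residue_uid, atoms.is_ca):
        chain, seq, resname = uid.split(":")
        name = "CA" if is_ca else "C"
        lines.append(
            f"ATOM  {serial:5d} {(' ' + name):<4s}{resname:>3s} {chain}"
            f"{int(seq):4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {name[0]:>2s}"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
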