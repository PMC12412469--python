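"""Dot-surface construction, loading, inflation, and synthetic fixtures.

A molecular surface is represented as a *dot surface*: one point per
triangle face of a triangulated surface, placed at the face centroid,
carrying the outward unit face normal and the face area.  The target
working density is ~20 dots per Å², at which scale a local patch of the
surface is densely sampled enough for histogram fingerprinting without
interpolation.

Two routes produce a dot surface from a structure: ingesting an
externally triangulated mesh (OBJ/PLY), or the internal fallback that
builds a marching-cubes isosurface of a smoothed atomic density.  The
module also synthesizes closed analytic surfaces — spheres and
"split-solid" pairs whose interface patches are exactly complementary
with known point correspondences — so the whole pipeline is testable
without any external input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

from .structures import StructureAtoms, load_structure

__all__ = [
    "TriMesh",
    "DotSurface",
    "mesh_to_dots",
    "inflate_surface",
    "load_mesh",
    "load_structure_surface",
    "structure_to_surface",
    "make_sphere",
    "make_split_pair",
    "write_ply",
    "read_ply_dots",
]


@dataclass
class TriMesh:
    """Triangulated surface: vertices (Å) and faces (vertex index triples)."""

    vertices: np.ndarray
    faces: np.ndarray
    face_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.face_normals is not None:
            self.face_normals = np.asarray(self.face_normals, dtype=np.float64).reshape(-1, 3)
            if len(self.face_normals) != len(self.faces):
                raise ValueError("face_normals length must equal number of faces")

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class DotSurface:
    """Point-cloud surface: dot coordinates, outward unit normals, areas (Å²)."""

    points: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        self.areas = np.asarray(self.areas, dtype=np.float64).ravel()
        n = len(self.points)
        if not (len(self.normals) == len(self.areas) == n):
            raise ValueError("points, normals and areas must have equal length")
        if n:
            lengths = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(lengths, 1.0, atol=1e-6):
                raise ValueError("normals must be unit vectors (|n| = 1 ± 1e-6)")
            if np.any(self.areas <= 0):
                raise ValueError("all dot areas must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def density(self) -> float:
        """Realized dot density in dots per Å²."""
        return len(self) / self.total_area

    def subset(self, indices: np.ndarray, source_id: str | None = None) -> "DotSurface":
        return DotSurface(
            self.points[indices], self.normals[indices], self.areas[indices],
            source_id=self.source_id if source_id is None else source_id,
        )


# ---------------------------------------------------------------------------
# mesh -> dots


def _face_geometry(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroids, winding normals (unnormalized) and areas of all faces."""
    tri = mesh.vertices[mesh.faces]          # (m, 3, 3)
    centroids = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    return centroids, cross, areas


def _orient_outward(mesh: TriMesh, centroids: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Flip face normals so they point away from the enclosed volume.

    Connected components are handled independently: within each, the
    winding is assumed consistent, so a single majority vote of
    (dot - component centroid) · normal decides the global flip.
    """
    tmesh = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    labels = _trimesh.graph.connected_component_labels(tmesh.face_adjacency,
                                                       node_count=len(mesh.faces))
    out = normals.copy()
    for label in np.unique(labels):
        sel = labels == label
        center = centroids[sel].mean(axis=0)
        vote = np.einsum("ij,ij->i", centroids[sel] - center, out[sel]).sum()
        if vote < 0:
            out[sel] = -out[sel]
    return out


def mesh_to_dots(mesh: TriMesh, source_id: str = "") -> DotSurface:
    """Convert a triangulated surface to its dot-surface representation.

    One dot per face, at the face centroid, with the outward unit face
    normal and the face area.  Total dot area equals the mesh surface
    area by construction.

    Raises
    ------
    ValueError
        If any face is degenerate (zero area); the message names the
        first offending face index.
    """
    centroids, cross, areas = _face_geometry(mesh)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) face at index {bad[0]}")
    if mesh.face_normals is not None:
        normals = mesh.face_normals / np.linalg.norm(mesh.face_normals, axis=1, keepdims=True)
    else:
        normals = cross / (2.0 * areas[:, None])
        normals = _orient_outward(mesh, centroids, normals)
    return DotSurface(points=centroids, normals=normals, areas=areas, source_id=source_id)


def inflate_surface(surface: DotSurface, delta: float) -> DotSurface:
    """Displace every dot by ``delta`` Å along its own normal.

    Used (with the default 0.5 Å) to absorb coordinate uncertainty
    before fingerprint mapping; ``delta = 0`` is the identity.  Negative
    deltas deflate.  Normals and areas are carried over unchanged.
    """
    return DotSurface(
        points=surface.points + delta * surface.normals,
        normals=surface.normals.copy(),
        areas=surface.areas.copy(),
        source_id=surface.source_id,
    )


# ---------------------------------------------------------------------------
# file ingestion


def load_mesh(path: str | Path, source_id: str | None = None) -> TriMesh:
    """Load a triangulated surface from OBJ or PLY (ASCII or binary)."""
    path = Path(path)
    loaded = _trimesh.load(str(path), force="mesh", process=False)
    if loaded.faces is None or len(loaded.faces) == 0:
        raise ValueError(f"{path}: mesh has no faces (point clouds are not a surface)")
    return TriMesh(vertices=np.asarray(loaded.vertices), faces=np.asarray(loaded.faces))


def structure_to_surface(
    atoms: StructureAtoms,
    probe: float = 1.4,
    grid_spacing: float = 0.5,
    sharpness: float = 2.3,
) -> DotSurface:
    """Build a solvent-excluded-style dot surface from atoms.

    The fallback surface engine: a Gaussian atomic density is sampled on
    a regular grid with all radii dilated by the probe radius, the level
    set at density 1 is triangulated by marching cubes, and the
    resulting dot surface is deflated by the probe radius along its
    normals.  Dilate-then-erode by the probe approximates rolling a
    probe sphere over the van der Waals surface.  The default grid
    spacing is calibrated so realized dot density lands near 20 dots/Å².
    """
    from skimage import measure

    coords = atoms.coords
    radii = atoms.radii + probe
    pad = radii.max() + 2.0
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]

    density = np.zeros(shape, dtype=np.float32)
    # accumulate each atom's Gaussian only on its local sub-grid
    cutoff = 2.0  # in units of (dilated) atom radius
    for pos, r in zip(coords, radii):
        imin = np.maximum(((pos - cutoff * r - lo) / grid_spacing).astype(int), 0)
        imax = np.minimum(((pos + cutoff * r - lo) / grid_spacing).astype(int) + 2, shape)
        gx = axes[0][imin[0]:imax[0]] - pos[0]
        gy = axes[1][imin[1]:imax[1]] - pos[1]
        gz = axes[2][imin[2]:imax[2]] - pos[2]
        d2 = (gx[:, None, None] ** 2 + gy[None, :, None] ** 2 + gz[None, None, :] ** 2)
        density[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] += np.exp(
            -sharpness * (d2 / r**2 - 1.0)
        ).astype(np.float32)

    verts, faces, _, _ = measure.marching_cubes(density, level=1.0, spacing=(grid_spacing,) * 3)
    verts = verts + lo
    tm = _trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not tm.is_watertight:
        warnings.warn("fallback isosurface is not watertight; proceeding", stacklevel=2)
    if tm.volume < 0:
        tm.invert()
    # erode by the probe: move vertices inward along the *analytic*
    # density-gradient direction (the true surface normal of the smooth
    # isosurface, steadier than mesh vertex normals), then rebuild the
    # dot surface so face areas are those of the eroded geometry
    verts_d = np.asarray(tm.vertices)
    grad = np.zeros_like(verts_d)
    vtree = cKDTree(verts_d)
    for pos, r in zip(coords, radii):
        near = vtree.query_ball_point(pos, cutoff * r)
        if not near:
            continue
        d = verts_d[near] - pos
        g = np.exp(-sharpness * ((d**2).sum(axis=1) / r**2 - 1.0))
        grad[near] += d * (-2.0 * sharpness / r**2 * g)[:, None]
    out_dir = -grad / np.linalg.norm(grad, axis=1, keepdims=True)
    verts_in = verts_d - probe * out_dir
    faces = np.asarray(tm.faces)
    dilated_normals = np.asarray(tm.face_normals)
    mesh = TriMesh(vertices=verts_in, faces=faces)
    _, cross, areas = _face_geometry(mesh)
    keep = areas > 1e-12      # marching cubes emits slivers at voxel corners
    # strong erosion can crumple individual triangles and invert their
    # winding; re-orient each eroded face against its dilated parent
    normals = cross[keep] / (2.0 * areas[keep, None])
    flip = np.einsum("ij,ij->i", normals, dilated_normals[keep]) < 0
    normals[flip] = -normals[flip]
    mesh = TriMesh(vertices=verts_in, faces=faces[keep], face_normals=normals)
    return mesh_to_dots(mesh, source_id=atoms.source_id)


def load_structure_surface(
    path: str | Path,
    probe: float = 1.4,
    mesh_path: str | Path | None = None,
    grid_spacing: float = 0.5,
) -> DotSurface:
    """Dot surface for a structure file (PDB/mmCIF).

    If ``mesh_path`` is given, that externally produced triangulated
    surface (e.g. from a dedicated SES program) is ingested; otherwise
    the internal isosurface fallback is used.
    """
    path = Path(path)
    if mesh_path is not None:
        return mesh_to_dots(load_mesh(mesh_path), source_id=path.stem)
    atoms = load_structure(path)
    return structure_to_surface(atoms, probe=probe, grid_spacing=grid_spacing)


# ---------------------------------------------------------------------------
# synthetic fixtures


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def make_sphere(radius: float, density: float = 20.0, seed: int = 0,
                source_id: str = "sphere") -> DotSurface:
    """Closed spherical dot surface at a requested dot density.

    The dot count is ``round(4 pi r^2 * density)`` placed on a
    golden-angle spiral, so the realized density matches the request to
    rounding.  ``seed`` randomizes the sphere's orientation only, giving
    generic dot coordinates while keeping determinism.
    """
    if radius <= 0 or density <= 0:
        raise ValueError("radius and density must be positive")
    area = 4.0 * np.pi * radius**2
    n = max(8, int(round(area * density)))
    directions = _fibonacci_sphere(n)
    rng = np.random.default_rng(seed)
    rotation = _random_rotation(rng)
    directions = directions @ rotation.T
    return DotSurface(
        points=radius * directions,
        normals=directions,
        areas=np.full(n, area / n),
        source_id=source_id,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class _BumpField:
    """Smooth random height field f(x, y): a sum of Gaussian bumps."""

    def __init__(self, rng: np.random.Generator, extent: float, roughness: float,
                 n_bumps: int = 6):
        self.centers = rng.uniform(-0.8 * extent, 0.8 * extent, size=(n_bumps, 2))
        self.widths = rng.uniform(0.25 * extent, 0.6 * extent, size=n_bumps)
        amp = roughness * extent / 6.0
        self.amps = rng.uniform(-amp, amp, size=n_bumps)

    def __call__(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Heights f and gradients (df/dx, df/dy) at (m, 2) sample points."""
        diff = xy[:, None, :] - self.centers[None, :, :]           # (m, b, 2)
        r2 = (diff**2).sum(axis=2)
        g = self.amps[None, :] * np.exp(-r2 / (2.0 * self.widths[None, :] ** 2))
        f = g.sum(axis=1)
        grad = -(diff * (g / self.widths[None, :] ** 2)[:, :, None]).sum(axis=1)
        return f, grad


def make_split_pair(
    seed: int = 0,
    size: float = 14.0,
    roughness: float = 0.6,
    density: float = 20.0,
    core_margin: float = 10.5,
) -> tuple[DotSurface, DotSurface, np.ndarray]:
    """Split a spherical solid by a smooth random cut into two closed halves.

    The solid is a sphere of radius ``size`` (Å) cut by the surface
    z = f(x, y), where f is a seeded sum of Gaussian bumps with peak
    amplitude controlled by ``roughness``.  Half A occupies z > f(x, y);
    half B the complement.  Both halves carry their spherical cap plus
    the shared cut surface, sampled once, so the interface dots of A and
    B coincide exactly with antiparallel normals — exact steric
    complements with known correspondences.

    Returns ``(A, B, correspondences)`` where correspondences is an
    (m, 2) integer array of (index in A, index in B) of *certified core*
    interface dot pairs: those at least ``core_margin`` Å from the
    interface rim, whose local patches (at the default 10 Å radial span)
    see only complementary surface.  Closer to the rim the halves'
    outer shells enter the patch cylinder and dilute the fingerprint
    match, so rim pairs are coincident but not certified; if fewer than
    10 dots qualify, the 10 innermost interface dots are returned
    instead.  The whole construction is rotated by a seeded random
    rotation so dot coordinates are generic in the lab frame; A and B
    share that frame.

    Raises
    ------
    ValueError
        If the cut is too steep (max slope > 2), which risks a
        self-intersecting offset interface.
    """
    if size <= 0 or density <= 0:
        raise ValueError("size and density must be positive")
    rng = np.random.default_rng(seed)
    bumps = _BumpField(rng, extent=size, roughness=roughness)

    # reject pathological cuts: steep slopes break the offset-surface
    # geometry that complementarity relies on
    gx = np.linspace(-size, size, 41)
    grid = np.column_stack([m.ravel() for m in np.meshgrid(gx, gx)])
    _, grad = bumps(grid)
    max_slope = float(np.linalg.norm(grad, axis=1).max())
    if max_slope > 2.0:
        raise ValueError(f"cut too rough (max slope {max_slope:.2f} > 2); lower roughness")

    # spherical shell dots, assigned to halves by side of the cut;
    # built unrotated, the joint random rotation is applied at the end
    n_shell = max(8, int(round(4.0 * np.pi * size**2 * density)))
    directions = _fibonacci_sphere(n_shell)
    shell_pts = size * directions
    f_shell, _ = bumps(shell_pts[:, :2])
    upper = shell_pts[:, 2] > f_shell
    shell_area = 4.0 * np.pi * size**2 / n_shell

    # interface dots: two-pass grid sample of z = f(x, y) inside the sphere
    spacing0 = 1.0 / np.sqrt(density)
    ax0 = np.arange(-size, size + spacing0, spacing0)
    xy0 = np.column_stack([m.ravel() for m in np.meshgrid(ax0, ax0)])
    f0, grad0 = bumps(xy0)
    inside0 = (xy0**2).sum(axis=1) + f0**2 < size**2
    metric = np.sqrt(1.0 + (grad0[inside0] ** 2).sum(axis=1))
    mean_metric = float(metric.mean()) if inside0.any() else 1.0
    spacing = 1.0 / np.sqrt(density * mean_metric)

    ax = np.arange(-size, size + spacing, spacing)
    # half-offset staggering decorrelates the grid from the lab axes
    xv, yv = np.meshgrid(ax, ax)
    xv = xv + spacing * 0.5 * (np.arange(len(ax)) % 2)[:, None]
    xy = np.column_stack([xv.ravel(), yv.ravel()])
    f, grad = bumps(xy)
    inside = (xy**2).sum(axis=1) + f**2 < size**2
    xy, f, grad = xy[inside], f[inside], grad[inside]
    if len(xy) < 10:
        raise ValueError("interface too small: fewer than 10 interface dots")
    iface_pts = np.column_stack([xy, f])
    slope2 = (grad**2).sum(axis=1)
    iface_areas = spacing**2 * np.sqrt(1.0 + slope2)
    # outward normal of half A (solid above the cut) points downward
    n_a = np.column_stack([grad, -np.ones(len(grad))]) / np.sqrt(1.0 + slope2)[:, None]

    rotation = _random_rotation(rng)

    def assemble(cap_pts, cap_dirs, cap_mask, iface_normals, label):
        pts = np.vstack([cap_pts[cap_mask], iface_pts])
        nrm = np.vstack([cap_dirs[cap_mask], iface_normals])
        areas = np.concatenate([
            np.full(int(cap_mask.sum()), shell_area), iface_areas,
        ])
        return DotSurface(pts @ rotation.T, nrm @ rotation.T, areas, source_id=label)

    surf_a = assemble(shell_pts, directions, upper, n_a, f"split{seed}-A")
    surf_b = assemble(shell_pts, directions, ~upper, -n_a, f"split{seed}-B")
    rho = np.linalg.norm(iface_pts, axis=1)        # distance to solid center
    core = np.flatnonzero(rho < size - core_margin)
    if len(core) < 10:
        core = np.argsort(rho)[:10]
    correspondences = np.column_stack([
        int(upper.sum()) + core,
        int((~upper).sum()) + core,
    ])
    return surf_a, surf_b, correspondences


# ---------------------------------------------------------------------------
# PLY point-cloud output (for inspection in external viewers)

_PLY_HEADER = """\
ply
format ascii 1.0
comment hector dot surface{comment}
element vertex {n}
property double x
property double y
property double z
property double nx
property double ny
property double nz
property double area
end_header
"""


def write_ply(surface: DotSurface, path: str | Path) -> None:
    """Write the dot surface as an ASCII PLY point cloud with normals."""
    comment = f" source={surface.source_id}" if surface.source_id else ""
    data = np.column_stack([surface.points, surface.normals, surface.areas])
    with open(path, "w") as fh:
        fh.write(_PLY_HEADER.format(comment=comment, n=len(surface)))
        np.savetxt(fh, data, fmt="%.10g")


def read_ply_dots(path: str | Path, source_id: str = "") -> DotSurface:
    """Read back a dot-surface PLY written by :func:`write_ply`."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            if line.strip() == "end_header":
                break
        data = np.loadtxt(fh, ndmin=2)
    if n is None or data.shape != (n, 7):
        raise ValueError(f"{path}: expected {n} rows of 7 dot-surface columns")
    return DotSurface(data[:, :3], data[:, 3:6], data[:, 6], source_id=source_id)
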