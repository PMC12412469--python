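"""Rotation/translation-invariant 2-D surface-patch fingerprints.

A local patch is the set of surface dots inside a cylinder erected on a
center dot's outward normal (radius ``r_max``, height ``h_max``).  Each
member dot, expressed in the patch's local frame (origin at the center,
z along the normal), is projected to cylindrical coordinates

    (x, y, z)  ->  (r, theta, l)    with  r = sqrt(x^2 + y^2),  l = k z,

where the direction k = +1 produces a *forward* map (database subjects)
and k = -1 an *inverse* map (query epitopes): the inverse map of a patch
is the fingerprint of its ideal steric complement.  Integrating the
azimuth theta out — implemented as histogram accumulation over dots onto
an (r, l) grid — yields a fixed-size 2-D density map that is invariant
to rigid motion of the surface and to the arbitrary choice of the local
x/y axes.

Two published parameter generations are provided as presets:

======== ====== ====== ==== ======= ====== ============= =========
version  r_max  axial  res  stride  dot    post          inflation
         (Å)    span   (Å)  (freq)  skip   processing    (Å)
======== ====== ====== ==== ======= ====== ============= =========
v0.1     12     ±6     0.4  1:40    1:8    bilinear blur  0
v0.2     10     ±10    0.2  1:5     1      radial fading  0.5
======== ====== ====== ==== ======= ====== ============= =========
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.ndimage

from .surface import DotSurface

__all__ = [
    "MapParams",
    "SurfacePatch",
    "Fingerprint",
    "V01",
    "V02",
    "preset",
    "extract_patch",
    "project_cylindrical",
    "rasterize",
    "bilinear_smooth",
    "fade_weights",
    "fingerprint_patch",
    "fingerprint_surface",
    "FORWARD",
    "INVERSE",
]

FORWARD = +1
INVERSE = -1


@dataclass(frozen=True)
class MapParams:
    """Full parameterization of the fingerprint mapping.

    Parameters
    ----------
    r_max : float
        Radial span of the map in Å (bins cover [0, r_max)).
    h_max : float
        Total axial span in Å; the axial bins cover [-h_max/2, +h_max/2).
    resolution : float
        Bin edge length in Å; ``r_max`` and ``h_max`` must be integer
        multiples of it.
    map_frequency : int
        Stride between mapped patch centers (1:5 means every 5th dot).
    dot_stride : int
        Within-patch dot skipping (1:8 keeps every 8th member dot).
    interpolate : bool
        Apply the mass-conserving bilinear blur after binning (the
        first-generation smoothing, dropped once mapping density made
        maps smooth on their own).
    fade_radius_bins : int or None
        Radial bin index at which the sigmoidal edge fading reaches
        weight 1/2; ``None`` disables fading.
    fade_slope : float
        Steepness of the fading sigmoid (per radial bin).
    inflation : float
        Surface inflation in Å applied before mapping.
    version_tag : str
        Free-form label recorded with every fingerprint.
    """

    r_max: float
    h_max: float
    resolution: float
    map_frequency: int = 1
    dot_stride: int = 1
    interpolate: bool = False
    fade_radius_bins: int | None = None
    fade_slope: float = 0.0
    inflation: float = 0.0
    version_tag: str = "custom"

    def __post_init__(self) -> None:
        for span, name in ((self.r_max, "r_max"), (self.h_max, "h_max")):
            ratio = span / self.resolution
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of resolution")
        if self.map_frequency < 1 or self.dot_stride < 1:
            raise ValueError("strides must be >= 1")
        if self.fade_radius_bins is not None and self.fade_radius_bins > self.bins_r:
            raise ValueError("fade_radius_bins must not exceed bins_r")

    @property
    def bins_r(self) -> int:
        return int(round(self.r_max / self.resolution))

    @property
    def bins_l(self) -> int:
        return int(round(self.h_max / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bins_r, self.bins_l)

    def params_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in (
                "r_max", "h_max", "resolution", "map_frequency", "dot_stride",
                "interpolate", "fade_radius_bins", "fade_slope", "inflation",
            )},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "r_max": self.r_max, "h_max": self.h_max, "resolution": self.resolution,
            "map_frequency": self.map_frequency, "dot_stride": self.dot_stride,
            "interpolate": self.interpolate, "fade_radius_bins": self.fade_radius_bins,
            "fade_slope": self.fade_slope, "inflation": self.inflation,
            "version_tag": self.version_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MapParams":
        return cls(**d)


#: First-generation parameter set: coarse 30x30 maps with bilinear blur.
V01 = MapParams(r_max=12.0, h_max=12.0, resolution=0.4, map_frequency=40,
                dot_stride=8, interpolate=True, version_tag="v0.1")

#: Second-generation set: 50x100 maps at 0.2 Å, dense mapping, radial
#: fading (half-weight at bin 40, slope 0.3), 0.5 Å surface inflation.
V02 = MapParams(r_max=10.0, h_max=20.0, resolution=0.2, map_frequency=5,
                dot_stride=1, interpolate=False, fade_radius_bins=40,
                fade_slope=0.3, inflation=0.5, version_tag="v0.2")

_PRESETS = {"v01": V01, "v02": V02}


def preset(name: str) -> MapParams:
    """Look up a published parameter set by name ('v01' or 'v02')."""
    try:
        return _PRESETS[name.replace(".", "").lower()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass
class SurfacePatch:
    """Dots of one local patch, expressed in the patch's own frame."""

    center_index: int
    center: np.ndarray            # (3,) global coordinates, Å
    normal: np.ndarray            # (3,) unit vector, the local z-axis
    local_dots: np.ndarray        # (m, 3) member dots in the local frame
    local_weights: np.ndarray     # (m,) per-dot weights
    frame: np.ndarray             # (3, 3) rows = local x, y, z in global coords

    def to_global(self) -> np.ndarray:
        """Map local dots back to the global frame (inverse rigid transform)."""
        return self.local_dots @ self.frame + self.center

    def __len__(self) -> int:
        return len(self.local_dots)


@dataclass
class Fingerprint:
    """A 2-D (r, l) density map plus the provenance of its patch."""

    matrix: np.ndarray
    k: int
    center: np.ndarray
    normal: np.ndarray
    params_hash: str = ""
    source_id: str = ""
    patch_index: int = -1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D")
        if np.any(self.matrix < 0):
            raise ValueError("fingerprint entries must be non-negative")
        if self.k not in (FORWARD, INVERSE):
            raise ValueError("k must be +1 (forward) or -1 (inverse)")


def _orthonormal_completion(normal: np.ndarray) -> np.ndarray:
    """Any right-handed frame with the given z-axis (rows x, y, z).

    The azimuth is integrated out of every map, so the specific x/y
    choice is immaterial; this picks the axis least aligned with the
    normal for numerical robustness.
    """
    z = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(z))] = 1.0
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def extract_patch(
    surface: DotSurface,
    center_index: int,
    params: MapParams,
    frame: np.ndarray | None = None,
    use_areas: bool = False,
) -> SurfacePatch:
    """Collect the dots of the cylindrical patch around one center dot.

    Membership is strict: radial distance from the normal axis
    < ``r_max`` and |axial offset| < ``h_max/2``.  When
    ``params.dot_stride`` > 1 only every stride-th member (in surface
    index order) is kept.  ``frame`` may supply a specific x/y
    completion; by default an arbitrary one is built (the maps do not
    depend on it).
    """
    center = surface.points[center_index]
    normal = surface.normals[center_index]
    diff = surface.points - center
    z = diff @ normal
    r2 = np.maximum(np.einsum("ij,ij->i", diff, diff) - z * z, 0.0)
    members = np.flatnonzero((r2 < params.r_max**2) & (np.abs(z) < params.h_max / 2.0))
    if params.dot_stride > 1:
        members = members[:: params.dot_stride]
    if frame is None:
        frame = _orthonormal_completion(normal)
    local = diff[members] @ frame.T
    weights = surface.areas[members] if use_areas else np.ones(len(members))
    return SurfacePatch(
        center_index=center_index, center=center.copy(), normal=normal.copy(),
        local_dots=local, local_weights=weights, frame=frame,
    )


def project_cylindrical(patch: SurfacePatch, k: int = FORWARD) -> np.ndarray:
    """Cylindrical projection of the patch: (m, 3) array of (r, theta, l).

    l = k z flips the axial coordinate for inverse maps (k = -1), which
    describes the patch's ideal complementary surface.
    """
    x, y, z = patch.local_dots.T if len(patch) else (np.empty(0),) * 3
    return np.column_stack([np.hypot(x, y), np.arctan2(y, x), k * z])


def fade_weights(params: MapParams) -> np.ndarray:
    """Per-radial-bin sigmoidal fading weights (all ones when disabled).

    A logistic ramp evaluated at each bin's center index:
    w(i) = 1 / (1 + exp(slope * (i + 0.5 - fade_radius))), so weight is
    ~1 near the patch center, exactly 1/2 half a bin below the fade
    radius, and decays toward 0 at the patch rim.
    """
    if params.fade_radius_bins is None:
        return np.ones(params.bins_r)
    i = np.arange(params.bins_r)
    return 1.0 / (1.0 + np.exp(params.fade_slope * (i + 0.5 - params.fade_radius_bins)))


def rasterize(
    triples: np.ndarray,
    params: MapParams,
    weights: np.ndarray | None = None,
    *,
    k: int = FORWARD,
    center: np.ndarray | None = None,
    normal: np.ndarray | None = None,
    source_id: str = "",
    patch_index: int = -1,
) -> Fingerprint:
    """Accumulate projected dots into the (r, l) histogram fingerprint.

    The azimuth is integrated out by summing dot weights into half-open
    bins [i*res, (i+1)*res); the axial coordinate is shifted by +h_max/2
    so bin 0 starts at l = -h_max/2.  Inverse maps (k = -1) are binned
    as the exact axial mirror of the forward binning, so the
    inverse/forward duality holds bin-for-bin even for dots sitting
    exactly on a bin boundary (the patch center, at z = 0, always does).
    Edge fading multiplies each radial row by its sigmoid weight; the
    bilinear blur is applied afterwards when ``params.interpolate`` is
    set.

    Dots outside the map span violate the patch-membership contract and
    trigger an assertion rather than being clipped.
    """
    triples = np.asarray(triples, dtype=np.float64).reshape(-1, 3)
    matrix = np.zeros(params.shape)
    if len(triples):
        r, _, l = triples.T
        assert np.all((r < params.r_max) & (np.abs(l) < params.h_max / 2.0)), (
            "projected dot outside map span: patch membership contract violated"
        )
        ir = np.floor(r / params.resolution).astype(np.int64)
        z = k * l                                  # undo l = k z
        il = np.floor((z + params.h_max / 2.0) / params.resolution).astype(np.int64)
        if k == INVERSE:
            il = params.bins_l - 1 - il
        w = np.ones(len(triples)) if weights is None else np.asarray(weights, dtype=np.float64)
        np.add.at(matrix, (ir, il), w)
    matrix *= fade_weights(params)[:, None]
    if params.interpolate:
        matrix = bilinear_smooth(matrix)
    return Fingerprint(
        matrix=matrix, k=k,
        center=np.zeros(3) if center is None else np.asarray(center, dtype=float),
        normal=np.array([0.0, 0.0, 1.0]) if normal is None else np.asarray(normal, dtype=float),
        params_hash=params.params_hash(), source_id=source_id, patch_index=patch_index,
    )


# nearest-neighbour blur kernel: half the mass stays, the rest is shared
# equally by the four edge-adjacent bins
_BLUR_KERNEL = np.array([[0.0, 1.0, 0.0],
                         [1.0, 4.0, 1.0],
                         [0.0, 1.0, 0.0]]) / 8.0


def bilinear_smooth(matrix: np.ndarray) -> np.ndarray:
    """Local mass-conserving blur of a map (first-generation smoothing).

    Each bin shares half its mass with its four edge neighbours; edge
    handling reflects mass back into the map, so the total is conserved
    to machine precision and a constant map is a fixed point.
    """
    return scipy.ndimage.convolve(np.asarray(matrix, dtype=np.float64),
                                  _BLUR_KERNEL, mode="reflect")


def fingerprint_patch(
    patch: SurfacePatch,
    params: MapParams,
    k: int = FORWARD,
    source_id: str = "",
) -> Fingerprint:
    """Project and rasterize one patch (convenience wrapper)."""
    return rasterize(
        project_cylindrical(patch, k), params, patch.local_weights, k=k,
        center=patch.center, normal=patch.normal, source_id=source_id,
        patch_index=patch.center_index,
    )


def fingerprint_surface(
    surface: DotSurface,
    params: MapParams,
    k: int = FORWARD,
    use_areas: bool = False,
    center_indices: Sequence[int] | None = None,
    chunk: int = 256,
) -> list[Fingerprint]:
    """Fingerprint a whole surface: one map per mapped center.

    Centers are taken at dot indices 0, stride, 2*stride, ... with
    stride = ``params.map_frequency`` (so a 20 dots/Å² surface mapped at
    1:5 carries 4 maps/Å²), or at explicit ``center_indices``.  Surface
    inflation is *not* applied here — inflate first (see
    :func:`hector.surface.inflate_surface`) so the caller controls
    whether query and subject sides share it.

    Internally vectorized over blocks of centers; results agree with the
    per-patch route (differences can only arise from floating-point
    round-off for dots sitting exactly on a bin or patch boundary, which
    generic surfaces do not produce).
    """
    pts = surface.points
    n = len(pts)
    if center_indices is None:
        centers_idx = np.arange(0, n, params.map_frequency)
    else:
        centers_idx = np.asarray(center_indices, dtype=np.int64)
    dot_w = surface.areas if use_areas else np.ones(n)
    pts_sq = np.einsum("ij,ij->i", pts, pts)
    br, bl = params.shape
    fade = fade_weights(params)
    out: list[Fingerprint] = []
    for start in range(0, len(centers_idx), chunk):
        block = centers_idx[start:start + chunk]
        c = pts[block]                               # (b, 3)
        nrm = surface.normals[block]                 # (b, 3)
        z = nrm @ pts.T - np.einsum("ij,ij->i", nrm, c)[:, None]      # (b, n)
        d2 = pts_sq[None, :] - 2.0 * (c @ pts.T) + np.einsum("ij,ij->i", c, c)[:, None]
        r2 = np.maximum(d2 - z * z, 0.0)
        # the center dot is at the local origin *exactly*: its z = 0 sits on
        # a bin boundary (even bins_l), so round-off must not decide its bin
        rows_ = np.arange(len(block))
        z[rows_, block] = 0.0
        r2[rows_, block] = 0.0
        mask = (r2 < params.r_max**2) & (np.abs(z) < params.h_max / 2.0)
        if params.dot_stride > 1:
            order = np.cumsum(mask, axis=1)
            mask &= (order - 1) % params.dot_stride == 0
        rows, cols = np.nonzero(mask)
        ir = np.floor(np.sqrt(r2[rows, cols]) / params.resolution).astype(np.int64)
        il = np.floor((params.h_max / 2.0 + z[rows, cols]) / params.resolution).astype(np.int64)
        if k == INVERSE:
            il = bl - 1 - il           # exact axial mirror (duality convention)
        flat = np.bincount(rows * (br * bl) + ir * bl + il,
                           weights=dot_w[cols], minlength=len(block) * br * bl)
        maps = flat.reshape(len(block), br, bl) * fade[None, :, None]
        for j, ci in enumerate(block):
            matrix = bilinear_smooth(maps[j]) if params.interpolate else maps[j]
            out.append(Fingerprint(
                matrix=matrix, k=k, center=pts[ci].copy(),
                normal=surface.normals[ci].copy(), params_hash=params.params_hash(),
                source_id=surface.source_id, patch_index=int(ci),
            ))
    return out
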