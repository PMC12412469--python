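"""Fingerprint database: in-memory stack and single-file HDF5 container.

Maps are stored at 32-bit float precision (computation upstream and
scoring downstream stay 64-bit); geometry (patch centers and normals)
rides along so the search can apply distance constraints and clique
alignment without touching the original surfaces.  One file holds one
parameter set — mixing parameterizations in a database is an error, and
the parameter hash is checked on every append and load.

Files are written with HDF5 object-time tracking disabled, so building
the same database twice from the same inputs yields byte-identical
files (content-hash idempotence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .fingerprint import Fingerprint, MapParams

__all__ = ["FingerprintSet", "save_database", "load_database", "build_database"]

SCHEMA_VERSION = 1


@dataclass
class FingerprintSet:
    """Column-oriented stack of fingerprints from one or more surfaces."""

    matrices: np.ndarray          # (n, br, bl) float32
    centers: np.ndarray           # (n, 3) float64
    normals: np.ndarray           # (n, 3) float64
    source_ids: np.ndarray        # (n,) str
    patch_indices: np.ndarray     # (n,) int64
    k: int
    params: MapParams

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.float32)
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        self.source_ids = np.asarray(self.source_ids, dtype=object)
        self.patch_indices = np.asarray(self.patch_indices, dtype=np.int64)
        n = len(self.matrices)
        if not (len(self.centers) == len(self.normals) == len(self.source_ids)
                == len(self.patch_indices) == n):
            raise ValueError("FingerprintSet columns must have equal length")
        if n and self.matrices.shape[1:] != self.params.shape:
            raise ValueError("matrix shape does not match params")

    def __len__(self) -> int:
        return len(self.matrices)

    @classmethod
    def empty(cls, params: MapParams, k: int = +1) -> "FingerprintSet":
        br, bl = params.shape
        return cls(np.empty((0, br, bl), np.float32), np.empty((0, 3)),
                   np.empty((0, 3)), np.empty(0, object), np.empty(0, np.int64),
                   k=k, params=params)

    @classmethod
    def from_fingerprints(cls, fps: Sequence[Fingerprint], params: MapParams) -> "FingerprintSet":
        if not fps:
            return cls.empty(params)
        expected = params.params_hash()
        ks = {fp.k for fp in fps}
        if len(ks) != 1:
            raise ValueError("cannot mix forward and inverse maps in one set")
        for fp in fps:
            if fp.params_hash and fp.params_hash != expected:
                raise ValueError("fingerprint parameter hash does not match params")
        return cls(
            matrices=np.stack([fp.matrix for fp in fps]).astype(np.float32),
            centers=np.stack([fp.center for fp in fps]),
            normals=np.stack([fp.normal for fp in fps]),
            source_ids=np.array([fp.source_id for fp in fps], dtype=object),
            patch_indices=np.array([fp.patch_index for fp in fps], dtype=np.int64),
            k=ks.pop(), params=params,
        )

    def extend(self, other: "FingerprintSet") -> "FingerprintSet":
        if other.params.params_hash() != self.params.params_hash():
            raise ValueError("cannot mix parameter sets in one database")
        if len(other) and len(self) and other.k != self.k:
            raise ValueError("cannot mix forward and inverse maps in one database")
        return FingerprintSet(
            np.concatenate([self.matrices, other.matrices]),
            np.concatenate([self.centers, other.centers]),
            np.concatenate([self.normals, other.normals]),
            np.concatenate([self.source_ids, other.source_ids]),
            np.concatenate([self.patch_indices, other.patch_indices]),
            k=self.k if len(self) else other.k, params=self.params,
        )

    def subset(self, indices) -> "FingerprintSet":
        return FingerprintSet(
            self.matrices[indices], self.centers[indices], self.normals[indices],
            self.source_ids[indices], self.patch_indices[indices],
            k=self.k, params=self.params,
        )

    def source_labels(self) -> np.ndarray:
        """Integer structure labels (stable order of first appearance)."""
        _, inverse = np.unique(self.source_ids.astype(str), return_inverse=True)
        return inverse


def save_database(fset: FingerprintSet, path: str | Path) -> None:
    """Persist a fingerprint set to a single HDF5 file, deterministically."""
    path = Path(path)
    sources = fset.source_ids.astype(str)
    with h5py.File(path, "w", track_order=False) as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["params_json"] = json.dumps(fset.params.to_dict(), sort_keys=True)
        fh.attrs["params_hash"] = fset.params.params_hash()
        fh.attrs["k"] = fset.k
        opts = dict(track_times=False)
        # chunk maps per source structure so per-structure reads stay local
        order = np.argsort(sources, kind="stable")
        fh.create_dataset("matrices", data=fset.matrices[order], dtype="f4", **opts)
        fh.create_dataset("centers", data=fset.centers[order], **opts)
        fh.create_dataset("normals", data=fset.normals[order], **opts)
        fh.create_dataset("patch_indices", data=fset.patch_indices[order], **opts)
        fh.create_dataset("source_ids", data=sources[order].astype("S"), **opts)


def load_database(path: str | Path, expect_params: MapParams | None = None) -> FingerprintSet:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if int(fh.attrs["schema_version"]) != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported database schema version")
        params = MapParams.from_dict(json.loads(fh.attrs["params_json"]))
        if expect_params is not None and expect_params.params_hash() != params.params_hash():
            raise ValueError(f"{path}: database parameter set does not match the requested one")
        return FingerprintSet(
            matrices=fh["matrices"][...],
            centers=fh["centers"][...],
            normals=fh["normals"][...],
            source_ids=fh["source_ids"][...].astype(str).astype(object),
            patch_indices=fh["patch_indices"][...],
            k=int(fh.attrs["k"]),
            params=params,
        )


def build_database(
    surfaces: Iterable,
    params: MapParams,
    path: str | Path | None = None,
    k: int = +1,
    use_areas: bool = False,
    progress: bool = False,
) -> FingerprintSet:
    """Fingerprint many surfaces into one database (optionally persisted).

    Surface inflation from ``params.inflation`` is applied here, once,
    before mapping; an empty input list yields a valid empty database.
    """
    import logging

    from .fingerprint import fingerprint_surface
    from .surface import inflate_surface

    log = logging.getLogger("hector.db")
    fset = FingerprintSet.empty(params, k=k)
    for surface in surfaces:
        inflated = inflate_surface(surface, params.inflation) if params.inflation else surface
        fps = fingerprint_surface(inflated, params, k=k, use_areas=use_areas)
        fset = fset.extend(FingerprintSet.from_fingerprints(fps, params))
        if progress:
            log.info("mapped %s: %d patches (db total %d)",
                     surface.source_id or "<unnamed>", len(fps), len(fset))
    if path is not None:
        save_database(fset, path)
    return fset
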