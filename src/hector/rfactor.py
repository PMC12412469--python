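"""Complementarity scoring between inverse query and forward subject maps.

Two generations of the R-factor are provided.  The first measures the
normalized element-wise difference between sum-normalized maps (an L1
metric, 0 for identical-up-to-scale maps).  The second measures a
normalized overlap,

    R = -(1/N) * sum  (2 F I + C) / (F^2 + I^2 + C),

with N the number of matrix elements and C = 1e-4 a stability constant.
Each element of the sum lies in (0, 1] and equals 1 exactly when the two
entries match, so R is bounded in [-1, 0) and reaches -1 only for
identical maps.  The sign is negated relative to the raw overlap so that
*lower is better* in both generations, matching the cutoff conventions
used throughout the search (e.g. "average R-factor below -0.82").

All reductions accumulate in 64-bit regardless of the storage precision
of the database (which keeps maps at 32-bit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import Fingerprint

__all__ = ["RFactorConfig", "rfactor_v01", "rfactor_v02", "batch_rfactor"]

#: Default numerical-stability constant of the overlap R-factor.
DEFAULT_C = 1e-4


@dataclass(frozen=True)
class RFactorConfig:
    version: str = "v02"            # "v01" or "v02"
    C: float = DEFAULT_C
    v01_mode: str = "elementwise"   # see rfactor_v01

    def __post_init__(self) -> None:
        if self.version not in ("v01", "v02"):
            raise ValueError("version must be 'v01' or 'v02'")
        if self.C <= 0:
            raise ValueError("C must be positive")


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, Fingerprint):
        m = m.matrix
    return np.asarray(m, dtype=np.float64)


def rfactor_v01(F, I, mode: str = "elementwise") -> float:
    """First-generation R-factor: normalized map difference (>= 0).

    ``mode='elementwise'`` (default): sum of |F/sum(F) - I/sum(I)| over
    elements — zero for maps identical up to scale, larger for more
    dissimilar maps.  ``mode='crystallographic'`` instead mirrors the
    crystallographic convention sum|F - I| / sum(I); provided because the
    normalization is a genuine interpretation choice.

    Raises on an all-zero map: the normalization is undefined there.
    """
    F, I = _as_matrix(F), _as_matrix(I)
    if F.shape != I.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {I.shape}")
    sf, si = F.sum(), I.sum()
    if sf <= 0 or si <= 0:
        raise ValueError("R-factor undefined for an all-zero map")
    if mode == "elementwise":
        return float(np.abs(F / sf - I / si).sum())
    if mode == "crystallographic":
        return float(np.abs(F - I).sum() / si)
    raise ValueError(f"unknown mode {mode!r}")


def rfactor_v02(F, I, C: float = DEFAULT_C) -> float:
    """Overlap R-factor in [-1, 0): -1 iff F equals I element-wise."""
    F, I = _as_matrix(F), _as_matrix(I)
    if F.shape != I.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {I.shape}")
    overlap = (2.0 * F * I + C) / (F * F + I * I + C)
    return float(-overlap.mean())


def batch_rfactor(query, db: np.ndarray, config: RFactorConfig | None = None,
                  chunk: int = 2048) -> np.ndarray:
    """Score one or more query maps against a stacked database.

    Parameters
    ----------
    query : Fingerprint, (br, bl) array, or (q, br, bl) array
        Inverse query map(s).
    db : (n, br, bl) array
        Forward subject maps (any float dtype; computation is 64-bit).
    config : RFactorConfig
        Version and constants; defaults to the overlap R-factor.
    chunk : int
        Database rows processed per block, bounding peak memory.

    Returns
    -------
    (n,) array for a single query, (q, n) for multiple.  Matches the
    scalar operations to 1e-6 absolute (identically, up to summation
    order).
    """
    config = config or RFactorConfig()
    Q = _as_matrix(query)
    single = Q.ndim == 2
    if single:
        Q = Q[None]
    db = np.asarray(db)
    n = len(db)
    if n == 0:
        return np.empty((0,) if single else (len(Q), 0))
    if db.shape[1:] != Q.shape[1:]:
        raise ValueError(f"shape mismatch: db {db.shape[1:]} vs query {Q.shape[1:]}")
    nq = len(Q)
    nel = Q.shape[1] * Q.shape[2]
    Qf = Q.reshape(nq, nel)
    out = np.empty((nq, n))
    for start in range(0, n, chunk):
        block = db[start:start + chunk].astype(np.float64, copy=False).reshape(-1, nel)
        if config.version == "v02":
            F2 = block * block
            for qi in range(nq):
                I = Qf[qi]
                overlap = (2.0 * block * I + config.C) / (F2 + I * I + config.C)
                out[qi, start:start + len(block)] = -overlap.mean(axis=1)
        else:
            sf = block.sum(axis=1)
            if np.any(sf <= 0):
                raise ValueError("R-factor undefined for an all-zero map in the database")
            Fn = block / sf[:, None]
            for qi in range(nq):
                I = Qf[qi]
                si = I.sum()
                if si <= 0:
                    raise ValueError("R-factor undefined for an all-zero query map")
                if config.v01_mode == "elementwise":
                    out[qi, start:start + len(block)] = np.abs(Fn - I / si).sum(axis=1)
                else:
                    out[qi, start:start + len(block)] = np.abs(block - I).sum(axis=1) / si
    return out[0] if single else out
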