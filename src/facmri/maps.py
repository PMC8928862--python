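"""Derived parameter maps: fatty-acid fractions, fat fraction and T2*.

Under the assumption that fatty acids carry at most two double bonds, the
saturation fractions follow linearly from the fitted double-bond counts:

    fSFA  = 1 - (ndb - nmidb) / 3
    fMUFA = (ndb - 2 nmidb) / 3
    fPUFA = nmidb / 3

which sum to one identically.  The fat fraction is F / (W + F) on amplitude
magnitudes and T2* = 1 / R2*.  Invalid voxels carry NaN sentinels plus an
explicit boolean validity mask, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ParameterMaps",
    "FACMaps",
    "FractionResult",
    "fractions_from_double_bonds",
    "double_bonds_from_fractions",
    "fat_fraction",
    "t2star_map",
    "derive_fac_maps",
]


def _same_shape(*arrays: np.ndarray) -> bool:
    shapes = {np.shape(a) for a in arrays}
    return len(shapes) == 1


@dataclass
class ParameterMaps:
    """Voxel-wise fitted signal parameters on a shared grid.

    All arrays share one shape; voxels with ``valid == False`` hold NaN.
    ``affine`` maps voxel indices to world coordinates (NIfTI convention).
    """

    w_mag: np.ndarray
    f_mag: np.ndarray
    ndb: np.ndarray
    nmidb: np.ndarray
    psi_hz: np.ndarray
    r2star: np.ndarray
    residual_norm: np.ndarray
    valid: np.ndarray
    converged: np.ndarray | None = None
    clipped: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arrays = [
            self.w_mag, self.f_mag, self.ndb, self.nmidb,
            self.psi_hz, self.r2star, self.residual_norm, self.valid,
        ]
        if not _same_shape(*arrays):
            raise ValueError("all parameter maps must share one shape")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.w_mag.shape


@dataclass
class FACMaps:
    """Fatty-acid composition maps derived from :class:`ParameterMaps`."""

    fsfa: np.ndarray
    fmufa: np.ndarray
    fpufa: np.ndarray
    fat_fraction: np.ndarray
    t2star_s: np.ndarray
    valid: np.ndarray
    clipped: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if not _same_shape(self.fsfa, self.fmufa, self.fpufa,
                           self.fat_fraction, self.t2star_s, self.valid):
            raise ValueError("all FAC maps must share one shape")
        self.valid = np.asarray(self.valid, dtype=bool)


class FractionResult(NamedTuple):
    fsfa: np.ndarray
    fmufa: np.ndarray
    fpufa: np.ndarray
    #: True where a raw fraction fell outside [0, 1] and was clipped, which
    #: can only happen when the at-most-two-double-bonds assumption is
    #: violated by the inputs.
    clipped: np.ndarray


def fractions_from_double_bonds(ndb, nmidb) -> FractionResult:
    """SFA/MUFA/PUFA fractions from double-bond counts (vectorised).

    Raises ``ValueError`` when any input violates ndb >= 0 or
    0 <= nmidb <= ndb (NaN entries are passed through untouched).
    """
    ndb = np.asarray(ndb, dtype=float)
    nmidb = np.asarray(nmidb, dtype=float)
    finite = np.isfinite(ndb) & np.isfinite(nmidb)
    bad = finite & ((ndb < 0) | (nmidb < 0) | (nmidb > ndb))
    if np.any(bad):
        raise ValueError("require ndb >= 0 and 0 <= nmidb <= ndb")
    fsfa = 1.0 - (ndb - nmidb) / 3.0
    fmufa = (ndb - 2.0 * nmidb) / 3.0
    fpufa = nmidb / 3.0
    clipped = finite & (
        (fsfa < 0) | (fsfa > 1) | (fmufa < 0) | (fmufa > 1)
        | (fpufa < 0) | (fpufa > 1)
    )
    return FractionResult(
        np.clip(fsfa, 0.0, 1.0),
        np.clip(fmufa, 0.0, 1.0),
        np.clip(fpufa, 0.0, 1.0),
        clipped,
    )


def double_bonds_from_fractions(fsfa, fmufa, fpufa) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`fractions_from_double_bonds` on unclipped values.

    ndb = 3 (fMUFA + 2 fPUFA), nmidb = 3 fPUFA.
    """
    fmufa = np.asarray(fmufa, dtype=float)
    fpufa = np.asarray(fpufa, dtype=float)
    return 3.0 * (fmufa + 2.0 * fpufa), 3.0 * fpufa


def fat_fraction(w_mag, f_mag) -> tuple[np.ndarray, np.ndarray]:
    """Fat fraction F / (W + F) on amplitude magnitudes.

    Returns ``(ff, defined)`` where ``defined`` is False (and ff = 0) at
    voxels with W = F = 0.
    """
    w = np.asarray(w_mag, dtype=float)
    f = np.asarray(f_mag, dtype=float)
    if np.any((w < 0) | (f < 0)):
        raise ValueError("amplitude magnitudes must be non-negative")
    total = w + f
    defined = total > 0
    ff = np.divide(f, total, out=np.zeros_like(total), where=defined)
    return ff, defined


def t2star_map(r2star) -> np.ndarray:
    """T2* in seconds from R2* in 1/s; +inf sentinel where R2* = 0."""
    r2 = np.asarray(r2star, dtype=float)
    if np.any(r2[np.isfinite(r2)] < 0):
        raise ValueError("r2star must be non-negative")
    with np.errstate(divide="ignore"):
        return np.where(r2 > 0, 1.0 / np.where(r2 > 0, r2, 1.0), np.inf)


def derive_fac_maps(pmaps: ParameterMaps) -> FACMaps:
    """Voxel-wise FAC, fat-fraction and T2* maps from fitted parameters.

    Fractions are computed voxel-by-voxel (then averaged over ROIs by the
    segmentation module); the linear fraction formulas make that order
    interchangeable with averaging ndb/nmidb first.
    """
    valid = pmaps.valid.copy()
    nan = np.full(pmaps.shape, np.nan)

    ndb = np.where(valid, pmaps.ndb, 0.0)
    nmidb = np.where(valid, pmaps.nmidb, 0.0)
    frac = fractions_from_double_bonds(ndb, nmidb)

    w = np.where(valid, pmaps.w_mag, 0.0)
    f = np.where(valid, pmaps.f_mag, 0.0)
    ff, ff_defined = fat_fraction(w, f)
    valid = valid & ff_defined

    t2s = t2star_map(np.where(valid, pmaps.r2star, 1.0))

    def _masked(a: np.ndarray) -> np.ndarray:
        return np.where(valid, a, nan)

    return FACMaps(
        fsfa=_masked(frac.fsfa),
        fmufa=_masked(frac.fmufa),
        fpufa=_masked(frac.fpufa),
        fat_fraction=_masked(ff),
        t2star_s=np.where(valid, t2s, np.nan),
        valid=valid,
        clipped=frac.clipped & valid,
        affine=pmaps.affine.copy(),
    )
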