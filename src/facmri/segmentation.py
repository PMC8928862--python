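"""Adipose depot segmentation: SAT, VAT and the deep/superficial SAT split.

The subcutaneous depot is grown as the 4-connected component of
high-fat-fraction voxels around a seed in the subcutaneous ring; the
visceral depot comes from a manually supplied abdominal-cavity polygon
(minus SAT, so spinal and lean voxels that survive rasterisation are left
to the ROI refinement); the SAT ring is split into deep (dSAT, toward the
cavity) and superficial (sSAT, toward the skin) compartments along a
fascia polyline, restricted to the posterior (lower-row) half of the image
where the fascia can be followed reliably.  Analysis ROIs keep only voxels
with fat fraction above 0.9 (and below an optional 1.1 cap) and T2* above
20 ms.

Coordinates are 0-based (row, col) voxel indices; polygons and polylines
are sequences of (row, col) vertices in that index space, and a pixel
belongs to a polygon when its centre does (even-odd rule, half-open on
edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .maps import FACMaps, ParameterMaps, double_bonds_from_fractions

__all__ = [
    "DepotMasks",
    "DepotSummary",
    "region_grow_sat",
    "delineate_vat",
    "split_sat_depots",
    "refine_roi",
    "depot_mean_fac",
    "dice",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class DepotMasks:
    """Boolean masks for the adipose depots, on the map grid.

    Invariants: dSAT and sSAT are subsets of SAT; SAT and VAT are disjoint.
    ``provenance`` records how each mask was obtained (grown/manual/split).
    """

    sat: np.ndarray
    vat: np.ndarray
    dsat: np.ndarray | None = None
    ssat: np.ndarray | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.sat = np.asarray(self.sat, dtype=bool)
        self.vat = np.asarray(self.vat, dtype=bool)
        if self.sat.shape != self.vat.shape:
            raise ValueError("sat and vat masks must share one shape")
        if np.any(self.sat & self.vat):
            raise ValueError("sat and vat masks overlap")
        for name in ("dsat", "ssat"):
            mask = getattr(self, name)
            if mask is None:
                continue
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.sat.shape:
                raise ValueError(f"{name} shape mismatch")
            if np.any(mask & ~self.sat):
                raise ValueError(f"{name} must be a subset of sat")
            setattr(self, name, mask)


def region_grow_sat(
    fat_fraction_map: np.ndarray,
    seed_voxel: tuple[int, int] | None = None,
    growth_threshold: float = 0.5,
) -> np.ndarray:
    """Grow the subcutaneous mask from a seed in the fatty ring.

    Returns the 4-connected component of voxels with
    ``FF >= growth_threshold`` containing the seed.  With no seed given,
    the highest-FF voxel of the map is used (on a body-in-air slice the
    subcutaneous ring holds the global FF maximum).  NaN voxels never pass.
    """
    ff = np.asarray(fat_fraction_map, dtype=float)
    if ff.ndim != 2:
        raise ValueError("fat_fraction_map must be 2-D (one slice)")
    above = np.isfinite(ff) & (ff >= growth_threshold)
    if seed_voxel is None:
        if not np.any(np.isfinite(ff)):
            raise ValueError("fat-fraction map holds no finite voxels")
        seed_voxel = np.unravel_index(np.nanargmax(ff), ff.shape)
    r, c = (int(seed_voxel[0]), int(seed_voxel[1]))
    if not (0 <= r < ff.shape[0] and 0 <= c < ff.shape[1]):
        raise ValueError("seed voxel outside the image")
    if not above[r, c]:
        raise ValueError(
            f"seed voxel ({r}, {c}) has FF below the growth threshold "
            f"{growth_threshold}"
        )
    labels, _ = ndimage.label(above, structure=_FOUR_CONN)
    return labels == labels[r, c]


def _polygon_area(vertices: np.ndarray) -> float:
    r, c = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))


def rasterize_polygon(vertices: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centres fall inside the polygon (even-odd ray cast).

    Edges are treated half-open (a centre exactly on a lower edge is in,
    on the matching upper edge out), so adjacent polygons tile without
    overlap.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    if abs(_polygon_area(v)) < 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    inside = np.zeros(shape, dtype=bool)
    r1, c1 = v[:, 0], v[:, 1]
    r2, c2 = np.roll(r1, -1), np.roll(c1, -1)
    for a_r, a_c, b_r, b_c in zip(r1, c1, r2, c2):
        if a_r == b_r:
            continue
        crosses = (a_r <= rr) != (b_r <= rr)
        with np.errstate(invalid="ignore"):
            c_at = a_c + (rr - a_r) * (b_c - a_c) / (b_r - a_r)
        inside ^= crosses & (cc < c_at)
    return inside


def delineate_vat(
    cavity_polygon: Sequence[Sequence[float]],
    sat_mask: np.ndarray,
    fat_fraction_map: np.ndarray,
) -> np.ndarray:
    """Visceral mask: voxels inside the manually drawn cavity, outside SAT."""
    sat = np.asarray(sat_mask, dtype=bool)
    ff = np.asarray(fat_fraction_map, dtype=float)
    if sat.shape != ff.shape:
        raise ValueError("sat mask and fat-fraction map must share one shape")
    inside = rasterize_polygon(cavity_polygon, sat.shape)
    return inside & ~sat


def split_sat_depots(
    sat_mask: np.ndarray,
    fascia_polyline: Sequence[Sequence[float]],
    image_height: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split posterior SAT into deep and superficial compartments.

    Only SAT in the lower half of the image rows (the posterior side in a
    supine acquisition, where the fascia is separable) is used.  The fascia
    polyline (row, col vertices, interpolated linearly in column) divides it
    into dSAT (rows strictly above the fascia, toward the cavity) and sSAT
    (rows on or below it, toward the skin).
    """
    sat = np.asarray(sat_mask, dtype=bool)
    if sat.ndim != 2:
        raise ValueError("sat_mask must be 2-D")
    height = sat.shape[0] if image_height is None else int(image_height)
    poly = np.asarray(fascia_polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
        raise ValueError("fascia polyline needs at least 2 (row, col) vertices")

    lower = np.zeros_like(sat)
    lower[height // 2:, :] = True
    band = sat & lower
    dsat = np.zeros_like(sat)
    ssat = np.zeros_like(sat)
    if not np.any(band):
        return dsat, ssat

    order = np.argsort(poly[:, 1])
    knot_cols, knot_rows = poly[order, 1], poly[order, 0]
    rr, cc = np.nonzero(band)
    if cc.min() < knot_cols[0] - 0.5 or cc.max() > knot_cols[-1] + 0.5:
        raise ValueError(
            "fascia polyline does not span the posterior SAT band "
            f"(columns {cc.min()}..{cc.max()} vs polyline "
            f"{knot_cols[0]:.1f}..{knot_cols[-1]:.1f})"
        )
    fascia_row = np.interp(cc, knot_cols, knot_rows)
    deep = rr < fascia_row
    dsat[rr[deep], cc[deep]] = True
    ssat[rr[~deep], cc[~deep]] = True
    return dsat, ssat


def refine_roi(
    depot_mask: np.ndarray,
    fat_fraction_map: np.ndarray,
    t2star_map_s: np.ndarray,
    *,
    ff_min: float = 0.9,
    ff_max: float | None = 1.1,
    t2star_min_s: float = 0.020,
) -> np.ndarray:
    """Analysis ROI: depot voxels with FF > 0.9 and T2* > 20 ms.

    Inequalities are strict; ``ff_max`` additionally caps the fat fraction
    at 1.1 (inert for magnitude-derived FF <= 1, kept as a guard against
    numerical noise; pass None to disable).  Non-finite voxels are excluded.
    """
    mask = np.asarray(depot_mask, dtype=bool)
    ff = np.asarray(fat_fraction_map, dtype=float)
    t2s = np.asarray(t2star_map_s, dtype=float)
    if not mask.shape == ff.shape == t2s.shape:
        raise ValueError("mask and maps must share one shape")
    keep = mask & np.isfinite(ff) & (ff > ff_min) & (t2s > t2star_min_s)
    if ff_max is not None:
        keep &= ff < ff_max
    return keep


class DepotSummary(NamedTuple):
    fsfa: float
    fmufa: float
    fpufa: float
    ndb: float
    nmidb: float
    n_voxels: int


def depot_mean_fac(
    fac_maps: FACMaps,
    roi_mask: np.ndarray,
    param_maps: ParameterMaps | None = None,
) -> DepotSummary:
    """Arithmetic mean FAC over the valid voxels of one ROI.

    ndb/nmidb come from ``param_maps`` when given, otherwise from the exact
    linear inversion of the fraction maps (both orders agree because the
    fraction formulas are linear).
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != fac_maps.fsfa.shape:
        raise ValueError("roi mask shape mismatch")
    use = roi & fac_maps.valid
    n = int(use.sum())
    if n == 0:
        raise ValueError("ROI holds no valid voxels")
    fsfa = float(np.mean(fac_maps.fsfa[use]))
    fmufa = float(np.mean(fac_maps.fmufa[use]))
    fpufa = float(np.mean(fac_maps.fpufa[use]))
    if param_maps is not None:
        ndb = float(np.mean(param_maps.ndb[use]))
        nmidb = float(np.mean(param_maps.nmidb[use]))
    else:
        ndb_a, nmidb_a = double_bonds_from_fractions(fsfa, fmufa, fpufa)
        ndb, nmidb = float(ndb_a), float(nmidb_a)
    return DepotSummary(fsfa, fmufa, fpufa, ndb, nmidb, n)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / float(denom)
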