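"""Joint voxel-wise estimation of W, F, ndb, nmidb, field map and R2*.

The signal model is linear in the reparameterised complex amplitudes
``W, A0 = F f, A1 = F f ndb, A2 = F f nmidb`` once the nonlinear pair
(psi, R2*) is fixed, so the fit uses variable projection: for each trial
(psi, R2*) the four amplitudes are solved exactly by linear least squares
against the basis {1, P_F, P_ndb, P_nmidb} modulated by exp((i 2 pi psi -
R2*) t), and the residual of that subfit is the objective for the outer
2-parameter search.  A coarse multi-start grid over the field-map aliasing
interval avoids water-fat swap minima; a trust-region refinement then
polishes (psi, R2*).  Finally the amplitude ratios are mapped back to
(F, ndb, nmidb) with physical-range clipping.

Fitting is complex-valued throughout and voxel-wise independent (no spatial
field-map regularisation); given identical inputs and configuration the
result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .maps import ParameterMaps
from .spectral import (
    AcquisitionSpec,
    FatModelSpec,
    TriglycerideParams,
    basis_coefficients,
    resonance_amplitudes,
)

__all__ = [
    "FitConfig",
    "VoxelEstimate",
    "LinearSubfit",
    "design_basis",
    "linear_subfit",
    "nonlinear_map",
    "fit_voxel",
    "fit_image",
]


class RankDeficiencyError(ValueError):
    """Design matrix numerically singular (e.g. duplicate echo times)."""


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the voxel fit.

    ``psi_search_halfwidth_hz`` defaults to half the field-map aliasing
    bandwidth, 1 / (2 delta_te); with 1.56 ms echo spacing that is about
    320 Hz.  The coarse grid is ``psi_grid_points`` field-map values crossed
    with ``r2star_grid_points`` decay rates up to ``r2star_grid_max``.
    """

    psi_search_halfwidth_hz: float | None = None
    psi_grid_points: int = 64
    refine_starts: int = 3
    r2star_grid_points: int = 6
    r2star_grid_max: float = 300.0
    r2star_bounds: tuple[float, float] = (0.0, 500.0)
    max_iterations: int = 50
    convergence_tol: float = 1e-8
    min_signal_fraction: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.r2star_bounds
        if not lo < hi:
            raise ValueError("r2star_bounds must be ordered")
        if lo < 0:
            raise ValueError("r2star lower bound must be non-negative")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")
        if self.psi_grid_points < 1 or self.r2star_grid_points < 1:
            raise ValueError("grid sizes must be at least 1")
        if self.refine_starts < 1:
            raise ValueError("refine_starts must be at least 1")
        if not 0 <= self.min_signal_fraction < 1:
            raise ValueError("min_signal_fraction must be in [0, 1)")

    def halfwidth(self, acq: AcquisitionSpec) -> float:
        if self.psi_search_halfwidth_hz is not None:
            return self.psi_search_halfwidth_hz
        return 1.0 / (2.0 * acq.delta_te_s)


class LinearSubfit(NamedTuple):
    water: complex
    a0: complex  # F f
    a1: complex  # F f ndb
    a2: complex  # F f nmidb
    residual_norm: float


@dataclass(frozen=True)
class VoxelEstimate:
    """Fitted parameters of one voxel; amplitudes as magnitudes."""

    w_mag: float
    f_mag: float
    ndb: float
    nmidb: float
    psi_hz: float
    r2star: float
    residual_norm: float
    converged: bool
    clipped: bool = False


def design_basis(
    acq: AcquisitionSpec, spec: FatModelSpec, *, include_constant_ea: bool = False
) -> np.ndarray:
    """Undecayed design columns {1, P_F, P_ndb, P_nmidb}, shape (n_echoes, 4)."""
    t = acq.echo_times
    p_f, p_ndb, p_nmidb = basis_coefficients(
        t, spec, include_constant_ea=include_constant_ea
    )
    return np.column_stack([np.ones_like(t, dtype=complex), p_f, p_ndb, p_nmidb])


def _design(basis: np.ndarray, t: np.ndarray, psi_hz: float, r2star: float) -> np.ndarray:
    decay = np.exp((2j * np.pi * psi_hz - r2star) * t)
    return decay[:, None] * basis


def linear_subfit(
    signal: np.ndarray,
    psi_hz: float,
    r2star: float,
    acq: AcquisitionSpec,
    spec: FatModelSpec,
    *,
    basis: np.ndarray | None = None,
) -> LinearSubfit:
    """Exact least-squares amplitudes at fixed (psi, R2*).

    Solves ``min || s - D(psi, R2*) B a ||`` for the four complex amplitudes,
    where B holds the basis columns and D the field/decay modulation; the
    residual is measured against the unweighted acquired signal.
    """
    signal = np.asarray(signal, dtype=complex)
    t = acq.echo_times
    if signal.shape != t.shape:
        raise ValueError("signal length must match the number of echoes")
    if basis is None:
        basis = design_basis(acq, spec)
    a_mat = _design(basis, t, psi_hz, r2star)
    coef, _, rank, _ = np.linalg.lstsq(a_mat, signal, rcond=None)
    if rank < 4:
        raise RankDeficiencyError(
            "design matrix is rank deficient; check echo times"
        )
    resid = signal - a_mat @ coef
    return LinearSubfit(
        water=complex(coef[0]),
        a0=complex(coef[1]),
        a1=complex(coef[2]),
        a2=complex(coef[3]),
        residual_norm=float(np.linalg.norm(resid)),
    )


class NonlinearMap(NamedTuple):
    f_mag: float
    ndb: float
    nmidb: float
    clipped: bool
    degenerate: bool


def nonlinear_map(
    a0: complex, a1: complex, a2: complex, spec: FatModelSpec
) -> NonlinearMap:
    """Invert the linear reparameterisation back to (F, ndb, nmidb).

    ndb = Re(A1/A0) clipped to >= 0, nmidb = Re(A2/A0) clipped to [0, ndb],
    and F = A0 sum(alpha), i.e. F_mag = |A0| (104.8 - 2 ndb) at cl = 17.3.
    A voxel with |A0| at numerical-noise scale is reported fat-free rather
    than divided through.
    """
    scale = max(abs(a0), abs(a1), abs(a2))
    if scale == 0 or abs(a0) <= 1e3 * np.finfo(float).eps * scale:
        return NonlinearMap(0.0, 0.0, 0.0, False, True)
    ndb_raw = (a1 / a0).real
    nmidb_raw = (a2 / a0).real
    ndb = max(ndb_raw, 0.0)
    nmidb = min(max(nmidb_raw, 0.0), ndb)
    clipped = (ndb != ndb_raw) or (nmidb != nmidb_raw)
    # keep the bulk-methylene amplitude non-negative: 8 ndb - 2 nmidb <= 6(cl-4)
    mc = spec.methylene_constant
    if 8.0 * ndb - 2.0 * nmidb > mc:
        clipped = True
        shave = 1.0 - 1e-12  # keep strictly inside the feasible set
        bounded = shave * (mc + 2.0 * nmidb) / 8.0
        if nmidb <= bounded:
            ndb = bounded
        else:  # nmidb rides down with ndb; feasible corner at ndb = nmidb
            ndb = nmidb = shave * mc / 6.0
    alphas, _ = resonance_amplitudes(TriglycerideParams(ndb, nmidb), spec)
    return NonlinearMap(abs(a0) * float(alphas.sum()), ndb, nmidb, clipped, False)


def _fold_psi(psi_hz: float, acq: AcquisitionSpec) -> float:
    """Fold psi into the principal interval (-1/(2 dTE), 1/(2 dTE)]."""
    if not acq.uniform:
        return psi_hz
    period = 1.0 / acq.delta_te_s
    folded = psi_hz - period * np.round(psi_hz / period)
    if folded <= -period / 2.0:
        folded += period
    return float(folded)


def _psi_r2_grid(acq: AcquisitionSpec, cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    hw = cfg.halfwidth(acq)
    psis = np.linspace(-hw, hw, cfg.psi_grid_points, endpoint=False)
    r2s = np.linspace(0.0, cfg.r2star_grid_max, cfg.r2star_grid_points)
    r2s = np.clip(r2s, *cfg.r2star_bounds)
    return psis, r2s


def _refine(
    signal: np.ndarray,
    psi0: float,
    r20: float,
    t: np.ndarray,
    basis: np.ndarray,
    cfg: FitConfig,
    hw: float,
):
    """Trust-region polish of (psi, R2*) on the variable-projection residual.

    The optimiser works on scaled offsets from the start (x0 = 0), which
    keeps the trust-region initialisation and finite-difference steps well
    conditioned even for starts at psi = 0 or R2* = 0.
    """
    psi_scale = max(hw / 8.0, 1.0)
    r2_scale = 50.0

    def residual(u: np.ndarray) -> np.ndarray:
        a_mat = _design(basis, t, psi0 + u[0] * psi_scale, r20 + u[1] * r2_scale)
        coef, _, _, _ = np.linalg.lstsq(a_mat, signal, rcond=None)
        r = signal - a_mat @ coef
        return np.concatenate([r.real, r.imag])

    lo, hi = cfg.r2star_bounds
    # start strictly inside the R2* bounds: a start exactly on a bound makes
    # the trust-region solver open with a vanishing radius and stall
    margin = min(1.0, 0.25 * (hi - lo))
    r20 = min(max(r20, lo + margin), hi - margin)
    tol = cfg.convergence_tol
    result = least_squares(
        residual,
        x0=np.zeros(2),
        bounds=([-np.inf, (lo - r20) / r2_scale], [np.inf, (hi - r20) / r2_scale]),
        method="trf",
        ftol=tol, xtol=tol, gtol=tol,
        max_nfev=cfg.max_iterations * 4,
    )
    psi = psi0 + float(result.x[0]) * psi_scale
    r2 = min(max(r20 + float(result.x[1]) * r2_scale, lo), hi)
    return psi, r2, bool(result.status > 0)


def _candidate_starts(
    signals: np.ndarray,
    t: np.ndarray,
    basis: np.ndarray,
    psis: np.ndarray,
    r2s: np.ndarray,
    n_starts: int,
    *,
    cyclic: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top candidate (psi, R2*) starts per voxel from the coarse grid.

    For each grid node the orthonormal column span Q of the design is
    computed once and the subfit residual of every voxel follows as
    ||s||^2 - ||Q^H s||^2.  Along psi the residual landscape has several
    basins (the water-fat swap ambiguity), so up to ``n_starts`` local
    minima of the per-voxel psi profile are returned, best first, each
    paired with its best grid R2*.  ``cyclic`` treats the psi axis as
    periodic (true when the grid spans the full aliasing interval).

    Returns (psi, r2, residual) arrays of shape (n_vox, n_starts); absent
    candidates carry residual = +inf.
    """
    n_psi, n_r2, n_vox = psis.size, r2s.size, signals.shape[1]
    s_norm2 = np.sum(np.abs(signals) ** 2, axis=0)
    res2 = np.empty((n_psi, n_r2, n_vox))
    for i, psi in enumerate(psis):
        for j, r2 in enumerate(r2s):
            a_mat = _design(basis, t, float(psi), float(r2))
            q, _ = np.linalg.qr(a_mat)
            proj2 = np.sum(np.abs(q.conj().T @ signals) ** 2, axis=0)
            res2[i, j] = np.maximum(s_norm2 - proj2, 0.0)
    prof = res2.min(axis=1)  # (n_psi, n_vox)
    arg_r2 = res2.argmin(axis=1)
    if cyclic and n_psi > 2:
        left = np.roll(prof, 1, axis=0)
        right = np.roll(prof, -1, axis=0)
    else:
        pad = np.full((1, n_vox), np.inf)
        left = np.vstack([pad, prof[:-1]])
        right = np.vstack([prof[1:], pad])
    is_min = (prof <= left) & (prof <= right)
    masked = np.where(is_min, prof, np.inf)
    k = min(n_starts, n_psi)
    order = np.argsort(masked, axis=0, kind="stable")[:k]  # (k, n_vox)
    cols = np.arange(n_vox)
    cand_psi = psis[order]
    cand_r2 = r2s[arg_r2[order, cols]]
    cand_res = np.sqrt(masked[order, cols])
    return cand_psi.T, cand_r2.T, cand_res.T


def _fit_from_candidates(
    signal: np.ndarray,
    candidates: np.ndarray,
    acq: AcquisitionSpec,
    spec: FatModelSpec,
    cfg: FitConfig,
    basis: np.ndarray,
) -> VoxelEstimate:
    """Refine each candidate start and keep the lowest-residual solution.

    A candidate whose coarse-grid residual exceeds ten times the best
    refined residual (with a floor at numerical-noise scale) cannot
    plausibly win and is skipped; the generous factor covers grid
    quantisation of a basin that refinement would still descend deeply.
    """
    t = acq.echo_times
    hw = cfg.halfwidth(acq)
    snorm = float(np.linalg.norm(signal))
    best: tuple[float, float, float, bool] | None = None  # (res, psi, r2, conv)
    for psi0, r20, grid_res in candidates:
        if not np.isfinite(grid_res):
            continue
        if best is not None and grid_res > max(10.0 * best[0], 1e-9 * snorm):
            continue
        psi, r2, converged = _refine(signal, float(psi0), float(r20), t, basis, cfg, hw)
        res = linear_subfit(signal, psi, r2, acq, spec, basis=basis).residual_norm
        if best is None or res < best[0]:
            best = (res, psi, r2, converged)
    assert best is not None
    psi = _fold_psi(best[1], acq)
    sub = linear_subfit(signal, psi, best[2], acq, spec, basis=basis)
    nl = nonlinear_map(sub.a0, sub.a1, sub.a2, spec)
    return VoxelEstimate(
        w_mag=abs(sub.water),
        f_mag=nl.f_mag,
        ndb=nl.ndb,
        nmidb=nl.nmidb,
        psi_hz=psi,
        r2star=best[2],
        residual_norm=sub.residual_norm,
        converged=best[3],
        clipped=nl.clipped,
    )


def _grid_is_cyclic(acq: AcquisitionSpec, cfg: FitConfig) -> bool:
    if not acq.uniform:
        return False
    hw = cfg.halfwidth(acq)
    return abs(2.0 * hw * acq.delta_te_s - 1.0) < 1e-9


def fit_voxel(
    signal: np.ndarray,
    acq: AcquisitionSpec,
    spec: FatModelSpec,
    cfg: FitConfig | None = None,
    *,
    basis: np.ndarray | None = None,
    initial: tuple[float, float] | None = None,
) -> VoxelEstimate:
    """Fit one voxel's multi-echo signal.

    Multi-start over the field-map grid (the best few local minima of the
    variable-projection residual, guarding against water-fat swaps),
    followed by trust-region refinement of (psi, R2*); never raises on
    poor data — non-convergence returns the best iterate flagged
    ``converged=False``.  ``initial`` bypasses the grid stage with a single
    explicit start.
    """
    cfg = cfg or FitConfig()
    signal = np.asarray(signal, dtype=complex)
    t = acq.echo_times
    if signal.shape != t.shape:
        raise ValueError("signal length must match the number of echoes")
    if basis is None:
        basis = design_basis(acq, spec)

    if initial is None:
        psis, r2s = _psi_r2_grid(acq, cfg)
        c_psi, c_r2, c_res = _candidate_starts(
            signal[:, None], t, basis, psis, r2s, cfg.refine_starts,
            cyclic=_grid_is_cyclic(acq, cfg),
        )
        candidates = np.column_stack([c_psi[0], c_r2[0], c_res[0]])
    else:
        candidates = np.array([[initial[0], initial[1], 0.0]])
    return _fit_from_candidates(signal, candidates, acq, spec, cfg, basis)


def fit_image(
    data: np.ndarray,
    acq: AcquisitionSpec,
    spec: FatModelSpec,
    cfg: FitConfig | None = None,
    *,
    affine: np.ndarray | None = None,
) -> ParameterMaps:
    """Voxel-by-voxel fit of a multi-echo image.

    ``data`` is complex with the echo dimension first (echo, ...spatial).
    Voxels whose peak magnitude falls below ``min_signal_fraction`` of the
    image peak are marked invalid (NaN in every map) and skipped.
    """
    cfg = cfg or FitConfig()
    data = np.asarray(data, dtype=complex)
    if data.shape[0] != acq.n_echoes:
        raise ValueError(
            f"echo dimension {data.shape[0]} does not match acquisition "
            f"n_echoes={acq.n_echoes}"
        )
    spatial = data.shape[1:]
    signals = data.reshape(acq.n_echoes, -1)
    n_vox = signals.shape[1]

    peak = np.max(np.abs(signals), axis=0)
    global_peak = float(peak.max()) if n_vox else 0.0
    valid = peak >= cfg.min_signal_fraction * global_peak if global_peak > 0 else np.zeros(n_vox, bool)

    t = acq.echo_times
    basis = design_basis(acq, spec)
    out = {
        name: np.full(n_vox, np.nan)
        for name in ("w_mag", "f_mag", "ndb", "nmidb", "psi_hz", "r2star", "residual_norm")
    }
    converged = np.zeros(n_vox, dtype=bool)
    clipped = np.zeros(n_vox, dtype=bool)

    idx = np.flatnonzero(valid)
    if idx.size:
        psis, r2s = _psi_r2_grid(acq, cfg)
        c_psi, c_r2, c_res = _candidate_starts(
            signals[:, idx], t, basis, psis, r2s, cfg.refine_starts,
            cyclic=_grid_is_cyclic(acq, cfg),
        )
        for j, vox in enumerate(idx):
            candidates = np.column_stack([c_psi[j], c_r2[j], c_res[j]])
            est = _fit_from_candidates(
                signals[:, vox], candidates, acq, spec, cfg, basis
            )
            out["w_mag"][vox] = est.w_mag
            out["f_mag"][vox] = est.f_mag
            out["ndb"][vox] = est.ndb
            out["nmidb"][vox] = est.nmidb
            out["psi_hz"][vox] = est.psi_hz
            out["r2star"][vox] = est.r2star
            out["residual_norm"][vox] = est.residual_norm
            converged[vox] = est.converged
            clipped[vox] = est.clipped

    def _shaped(a: np.ndarray) -> np.ndarray:
        return a.reshape(spatial)

    return ParameterMaps(
        w_mag=_shaped(out["w_mag"]),
        f_mag=_shaped(out["f_mag"]),
        ndb=_shaped(out["ndb"]),
        nmidb=_shaped(out["nmidb"]),
        psi_hz=_shaped(out["psi_hz"]),
        r2star=_shaped(out["r2star"]),
        residual_norm=_shaped(out["residual_norm"]),
        valid=_shaped(valid.copy()),
        converged=_shaped(converged),
        clipped=_shaped(clipped),
        affine=np.eye(4) if affine is None else np.asarray(affine, float),
    )
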