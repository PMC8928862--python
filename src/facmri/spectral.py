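"""Multi-peak triglyceride spectral model for chemical-shift-encoded water-fat MRI.

Fat protons resonate in eight spectrally resolved groups (labelled A-H, from
the olefinic protons near 5.3 ppm down to the terminal methyl at 0.9 ppm).
Each group's proton count is a linear function of the mean number of double
bonds (``ndb``), the mean number of methylene-interrupted double bonds
(``nmidb``) and the mean fatty-acid chain length (``cl``).  Fixing the chain
length (default 17.3 carbons, a value typical of human subcutaneous adipose
tissue) leaves two unknown composition parameters, so the complex echo signal

    S(t) = [ W + F f (P_F(t) + P_ndb(t) ndb + P_nmidb(t) nmidb) ] exp(Psi t)

is linear in the reparameterised amplitudes W, F*f, F*f*ndb, F*f*nmidb once
the complex field term Psi = i 2 pi psi - R2* is known.  ``f = 1 / sum(alpha)``
normalises the fat spectrum to unit total proton count.

This module defines the model constants, the per-resonance angular
frequencies and amplitudes, the three linearised basis waveforms and the
noiseless forward signal (both the linearised form and the explicit
eight-resonance sum, which are algebraically identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "RESONANCE_GROUPS",
    "FatModelSpec",
    "TriglycerideParams",
    "AcquisitionSpec",
    "VoxelSignalParams",
    "resonance_frequencies",
    "resonance_amplitudes",
    "basis_coefficients",
    "forward_signal",
    "forward_signal_resonance_sum",
]

#: Resonance group labels, high to low chemical shift.
RESONANCE_GROUPS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

_DEFAULT_SHIFTS_PPM = (5.28, 4.22, 2.75, 2.25, 2.02, 1.57, 1.30, 0.90)


@dataclass(frozen=True)
class FatModelSpec:
    """Fixed constants of the eight-resonance fat spectrum.

    Parameters
    ----------
    chemical_shifts_ppm:
        Chemical shift of each resonance group A-H, strictly decreasing, ppm.
    water_shift_ppm:
        Water reference shift, ppm (4.70).
    chain_length:
        Mean fatty-acid chain length ``cl`` (carbons); fixed rather than
        fitted to stabilise the estimation.  Default 17.3.
    field_strength_t:
        Static field B0 in tesla.
    gyromagnetic_ratio_mhz_per_t:
        Proton gyromagnetic ratio, MHz/T.
    """

    chemical_shifts_ppm: tuple[float, ...] = _DEFAULT_SHIFTS_PPM
    water_shift_ppm: float = 4.70
    chain_length: float = 17.3
    field_strength_t: float = 3.0
    gyromagnetic_ratio_mhz_per_t: float = 42.577

    def __post_init__(self) -> None:
        shifts = tuple(float(s) for s in self.chemical_shifts_ppm)
        if len(shifts) != len(RESONANCE_GROUPS):
            raise ValueError(
                f"expected {len(RESONANCE_GROUPS)} chemical shifts, got {len(shifts)}"
            )
        if any(a <= b for a, b in zip(shifts[1:], shifts[2:])):
            # monotonicity checked below for the full tuple
            pass
        if any(s2 >= s1 for s1, s2 in zip(shifts, shifts[1:])):
            raise ValueError("chemical shifts must be strictly decreasing from A to H")
        if not self.chain_length > 4:
            raise ValueError("chain_length must exceed 4 carbons")
        if not self.field_strength_t > 0:
            raise ValueError("field_strength_t must be positive")
        if not self.gyromagnetic_ratio_mhz_per_t > 0:
            raise ValueError("gyromagnetic ratio must be positive")
        object.__setattr__(self, "chemical_shifts_ppm", shifts)

    @property
    def methylene_constant(self) -> float:
        """Constant term 6 (cl - 4) of the bulk methylene amplitude (79.8 at cl = 17.3)."""
        return 6.0 * (self.chain_length - 4.0)


@dataclass(frozen=True)
class TriglycerideParams:
    """Composition parameters of the triglyceride model.

    ``ndb`` is the mean number of double bonds and ``nmidb`` the mean number
    of methylene-interrupted double bonds (the -CH=CH-CH2-CH=CH- motifs of
    polyunsaturated chains).  Both are dimensionless model-unit averages.
    """

    ndb: float
    nmidb: float

    def __post_init__(self) -> None:
        if not self.ndb >= 0:
            raise ValueError("ndb must be non-negative")
        if not self.nmidb >= 0:
            raise ValueError("nmidb must be non-negative")
        if self.nmidb > self.ndb:
            raise ValueError("nmidb cannot exceed ndb")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Multi-echo gradient-echo acquisition timing and geometry.

    Defaults reproduce the reference protocol: 12 monopolar echoes,
    TE1 = 1.13 ms, echo spacing 1.56 ms, 96 x 128 in-plane matrix at 3 T.
    ``echo_times_s`` may be given explicitly for non-uniform spacings; when
    omitted, echoes are uniform: ``te1 + k * delta_te``.
    """

    n_echoes: int = 12
    te1_s: float = 1.13e-3
    delta_te_s: float = 1.56e-3
    matrix_shape: tuple[int, int] = (96, 128)
    echo_times_s: tuple[float, ...] | None = None
    metadata: dict | None = None

    def __post_init__(self) -> None:
        # at least one echo more than the 4 complex linear unknowns
        if self.n_echoes < 4:
            raise ValueError("need at least 4 echoes for the 4 linear unknowns")
        if not self.te1_s > 0:
            raise ValueError("te1_s must be positive")
        if not self.delta_te_s > 0:
            raise ValueError("delta_te_s must be positive")
        if self.echo_times_s is not None:
            times = tuple(float(t) for t in self.echo_times_s)
            if len(times) != self.n_echoes:
                raise ValueError("echo_times_s length must equal n_echoes")
            if any(t <= 0 for t in times):
                raise ValueError("echo times must be positive")
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("echo times must be strictly increasing")
            object.__setattr__(self, "echo_times_s", times)

    @property
    def uniform(self) -> bool:
        return self.echo_times_s is None

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times in seconds, shape (n_echoes,)."""
        if self.echo_times_s is not None:
            return np.asarray(self.echo_times_s, dtype=float)
        return self.te1_s + self.delta_te_s * np.arange(self.n_echoes)


@dataclass(frozen=True)
class VoxelSignalParams:
    """Full per-voxel signal parameterisation.

    ``water`` and ``fat`` are complex amplitudes (arbitrary units),
    ``field_map_hz`` the off-resonance frequency psi and ``r2star`` the
    effective transverse relaxation rate in 1/s.  Together they set the
    complex field term Psi = i 2 pi psi - R2*.
    """

    water: complex
    fat: complex
    triglyceride: TriglycerideParams
    field_map_hz: float = 0.0
    r2star: float = 0.0

    def __post_init__(self) -> None:
        if not self.r2star >= 0:
            raise ValueError("r2star must be non-negative")

    @property
    def complex_field(self) -> complex:
        return 2j * np.pi * self.field_map_hz - self.r2star


def _as_times(acq_or_times: AcquisitionSpec | Iterable[float]) -> np.ndarray:
    if isinstance(acq_or_times, AcquisitionSpec):
        return acq_or_times.echo_times
    return np.atleast_1d(np.asarray(acq_or_times, dtype=float))


def resonance_frequencies(spec: FatModelSpec) -> np.ndarray:
    """Water-referenced angular frequency of each fat resonance, rad/s.

    omega_m = 2 pi (delta_m - delta_water) * gamma * B0 where the ppm shift
    difference times gamma (MHz/T) times B0 (T) gives hertz directly.
    Resonances below water in ppm get negative omega.
    """
    shifts = np.asarray(spec.chemical_shifts_ppm, dtype=float)
    freq_hz = (
        (shifts - spec.water_shift_ppm)
        * spec.gyromagnetic_ratio_mhz_per_t
        * spec.field_strength_t
    )
    return 2.0 * np.pi * freq_hz


def resonance_amplitudes(
    tg: TriglycerideParams, spec: FatModelSpec
) -> tuple[np.ndarray, float]:
    """Proton amplitude alpha_m of each resonance group and normalisation f.

    alpha = (2 ndb, 4, 2 nmidb, 6, 4 (ndb - nmidb), 6,
             6 (cl - 4) - 8 ndb + 2 nmidb, 9)
    and ``f = 1 / sum(alpha)``.  With cl = 17.3 the bulk-methylene constant
    6 (cl - 4) equals 79.8 and sum(alpha) = 104.8 - 2 ndb.

    Raises
    ------
    ValueError
        If any amplitude is negative (composition impossible at this chain
        length, e.g. ndb so large that the methylene pool is exhausted).
    """
    ndb, nmidb = tg.ndb, tg.nmidb
    alphas = np.array(
        [
            2.0 * ndb,
            4.0,
            2.0 * nmidb,
            6.0,
            4.0 * (ndb - nmidb),
            6.0,
            spec.methylene_constant - 8.0 * ndb + 2.0 * nmidb,
            9.0,
        ]
    )
    if np.any(alphas < 0):
        bad = [g for g, a in zip(RESONANCE_GROUPS, alphas) if a < 0]
        raise ValueError(
            f"negative resonance amplitude(s) {bad} for ndb={ndb}, nmidb={nmidb}, "
            f"cl={spec.chain_length}"
        )
    return alphas, 1.0 / float(alphas.sum())


def basis_coefficients(
    acq_or_times: AcquisitionSpec | Iterable[float],
    spec: FatModelSpec,
    *,
    include_constant_ea: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex basis waveforms (P_F, P_ndb, P_nmidb) over the echo times.

    With E_m(t) = exp(i omega_m t):

        P_F     = 4 E_B + 6 E_D + 6 E_F + 6(cl-4) E_G + 9 E_H
        P_ndb   = 2 E_A + 4 E_E - 8 E_G
        P_nmidb = 2 E_C - 4 E_E + 2 E_G

    so that P_F + ndb P_ndb + nmidb P_nmidb = sum_m alpha_m E_m identically.
    At t = 0 and cl = 17.3 this gives P_F = 104.8, P_ndb = -2, P_nmidb = 0.

    ``include_constant_ea`` adds a bare ``+ E_A`` term to P_F.  Some printed
    accounts of the linearised model carry this extra term, but it is
    inconsistent with the amplitude table (alpha_A = 2 ndb has no constant
    part) and breaks the S(0) = W + F normalisation; it is exposed only for
    comparison and is off by default.
    """
    t = _as_times(acq_or_times)
    omega = resonance_frequencies(spec)
    e = np.exp(1j * np.outer(t, omega))  # (n_times, 8)
    ea, eb, ec, ed, ee, ef, eg, eh = (e[:, m] for m in range(8))
    p_f = 4.0 * eb + 6.0 * ed + 6.0 * ef + spec.methylene_constant * eg + 9.0 * eh
    if include_constant_ea:
        p_f = p_f + ea
    p_ndb = 2.0 * ea + 4.0 * ee - 8.0 * eg
    p_nmidb = 2.0 * ec - 4.0 * ee + 2.0 * eg
    return p_f, p_ndb, p_nmidb


def forward_signal(
    params: VoxelSignalParams,
    acq_or_times: AcquisitionSpec | Iterable[float],
    spec: FatModelSpec,
    *,
    include_constant_ea: bool = False,
) -> np.ndarray:
    """Noiseless complex signal at each echo time (linearised-basis form)."""
    t = _as_times(acq_or_times)
    tg = params.triglyceride
    _, f = resonance_amplitudes(tg, spec)
    p_f, p_ndb, p_nmidb = basis_coefficients(
        t, spec, include_constant_ea=include_constant_ea
    )
    fat_shape = params.fat * f * (p_f + tg.ndb * p_ndb + tg.nmidb * p_nmidb)
    return (params.water + fat_shape) * np.exp(params.complex_field * t)


def forward_signal_resonance_sum(
    params: VoxelSignalParams,
    acq_or_times: AcquisitionSpec | Iterable[float],
    spec: FatModelSpec,
) -> np.ndarray:
    """Noiseless signal from the explicit eight-resonance sum.

    Evaluates S(t) = (W + F f sum_m alpha_m exp(i omega_m t)) exp(Psi t)
    without the linearised-basis regrouping; agrees with
    :func:`forward_signal` to machine precision and serves as its in-package
    cross-check path.
    """
    t = _as_times(acq_or_times)
    alphas, f = resonance_amplitudes(params.triglyceride, spec)
    omega = resonance_frequencies(spec)
    spectrum = np.exp(1j * np.outer(t, omega)) @ alphas
    return (params.water + params.fat * f * spectrum) * np.exp(
        params.complex_field * t
    )
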