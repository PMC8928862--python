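"""Synthetic phantoms and two-group cohorts for the FAC pipeline.

The digital phantom emulates a single axial abdominal slice: an elliptical
body with a subcutaneous fat ring, a lean abdominal cavity containing a
circular visceral fat depot and a posterior spine wedge, a smooth low-order
polynomial field map, mono-exponential R2* decay and additive complex white
Gaussian noise.  Within each region the tissue parameters (fat fraction,
ndb, nmidb, R2*) are homogeneous; an optional fascia ellipse splits the
subcutaneous ring into deep and superficial shells with their own values.

The cohort generator draws per-subject, per-depot (ndb, nmidb) pairs from
group-level distributions — normals matched by median and interquartile
range to the reference two-group study (23 vs 15 subjects), truncated to
the physically valid region — and instantiates one phantom per subject.
Randomness is fully determined by an integer master seed with
counter-derived per-subject substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .maps import fractions_from_double_bonds
from .spectral import AcquisitionSpec, FatModelSpec, basis_coefficients

__all__ = [
    "RegionFat",
    "PhantomSpec",
    "GroundTruth",
    "DepotDistribution",
    "CohortSpec",
    "SubjectRecord",
    "generate_phantom",
    "draw_cohort_truth",
    "simulate_cohort",
    "default_cohort_spec",
]

# region labels in GroundTruth.labels
AIR, LEAN, SAT, VAT, SPINE, DSAT, SSAT = 0, 1, 2, 3, 4, 5, 6
LABEL_NAMES = {
    AIR: "air", LEAN: "lean", SAT: "sat", VAT: "vat",
    SPINE: "spine", DSAT: "dsat", SSAT: "ssat",
}


@dataclass(frozen=True)
class RegionFat:
    """Homogeneous tissue truth of one phantom region."""

    fat_fraction: float
    ndb: float
    nmidb: float
    r2star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must lie in [0, 1]")
        if not (self.ndb >= 0 and 0 <= self.nmidb <= self.ndb):
            raise ValueError("require ndb >= 0 and 0 <= nmidb <= ndb")
        if not self.r2star >= 0:
            raise ValueError("r2star must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue truth and noise level of the slice phantom.

    Distances are in voxels on the (rows, cols) grid.  ``snr`` is the ratio
    of the peak echo magnitude to the noise standard deviation per real
    channel; ``snr=None`` generates noiseless data.  Default tissue values
    sit mid-range of adult abdominal adipose tissue (FF ~0.95, ndb ~2.4,
    nmidb ~0.36, T2* ~29 ms) with a lean cavity at FF 0.10.
    """

    shape: tuple[int, int] = (96, 128)
    body_semiaxes: tuple[float, float] = (40.0, 56.0)
    sat_thickness: float = 10.0
    fascia_offset: float = 5.0
    visceral_offset: tuple[float, float] = (-4.0, 0.0)
    visceral_radius: float = 17.0
    spine_halfwidth: float = 9.0
    spine_height: float = 11.0
    sat: RegionFat = RegionFat(0.95, 2.40, 0.36, 35.0)
    vat: RegionFat = RegionFat(0.93, 2.30, 0.30, 40.0)
    lean: RegionFat = RegionFat(0.10, 2.30, 0.30, 30.0)
    dsat: RegionFat | None = None
    ssat: RegionFat | None = None
    signal_amplitude: float = 100.0
    field_map_poly_hz: tuple[float, ...] = (20.0, 10.0, -8.0, 5.0, 0.0, -5.0)
    snr: float | None = 50.0

    def __post_init__(self) -> None:
        if (self.dsat is None) != (self.ssat is None):
            raise ValueError("dsat and ssat truth must be given together")
        if self.sat_thickness <= 0 or not 0 < self.fascia_offset < self.sat_thickness:
            raise ValueError("require 0 < fascia_offset < sat_thickness")
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        if len(self.field_map_poly_hz) != 6:
            raise ValueError("field_map_poly_hz needs 6 coefficients (1,x,y,x^2,xy,y^2)")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


def _ellipse_mask(shape, center, semiaxes) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((rr - center[0]) / semiaxes[0]) ** 2 + (
        (cc - center[1]) / semiaxes[1]
    ) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Per-voxel truth maps plus the region label image and depot helpers."""

    labels: np.ndarray
    fat_fraction: np.ndarray
    ndb: np.ndarray
    nmidb: np.ndarray
    psi_hz: np.ndarray
    r2star: np.ndarray
    water: np.ndarray
    fat: np.ndarray
    spec: PhantomSpec

    @property
    def body(self) -> np.ndarray:
        return self.labels != AIR

    def depot_mask(self, name: str) -> np.ndarray:
        if name == "sat":
            return np.isin(self.labels, (SAT, DSAT, SSAT))
        label = {v: k for k, v in LABEL_NAMES.items()}[name]
        return self.labels == label

    def sat_seed(self) -> tuple[int, int]:
        """A voxel inside the subcutaneous ring (topmost ring voxel)."""
        rr, cc = np.nonzero(self.depot_mask("sat"))
        i = int(np.argmin(rr))
        return int(rr[i]), int(cc[i])

    def cavity_polygon(self, n_vertices: int = 720) -> np.ndarray:
        """Polygon tracing the abdominal cavity (inner ellipse), for VAT."""
        s = self.spec
        cr, cc = s.center
        a = s.body_semiaxes[0] - s.sat_thickness + 0.5
        b = s.body_semiaxes[1] - s.sat_thickness + 0.5
        theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        return np.column_stack([cr + a * np.sin(theta), cc + b * np.cos(theta)])

    def fascia_polyline(self, n_vertices: int = 361) -> np.ndarray:
        """Posterior fascia trace spanning the full image width.

        Follows the fascia ellipse over the posterior half and continues
        horizontally at the fascia equator out to the image edges, so the
        polyline spans every column of the posterior SAT band.
        """
        s = self.spec
        cr, cc = s.center
        a = s.body_semiaxes[0] - s.fascia_offset
        b = s.body_semiaxes[1] - s.fascia_offset
        theta = np.linspace(0.0, np.pi, n_vertices)  # posterior arc
        rows = cr + a * np.sin(theta)
        cols = cc + b * np.cos(theta)
        left = np.array([[cr, -1.0]])
        right = np.array([[cr, s.shape[1] + 0.0]])
        pts = np.vstack([right, np.column_stack([rows, cols]), left])
        return pts[::-1]


def _region_values(spec: PhantomSpec) -> dict[int, RegionFat]:
    values = {LEAN: spec.lean, VAT: spec.vat, SPINE: spec.lean}
    if spec.dsat is not None:
        values[DSAT] = spec.dsat
        values[SSAT] = spec.ssat
    else:
        values[SAT] = spec.sat
    return values


def build_truth(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the phantom geometry into truth maps (noise-free)."""
    shape = spec.shape
    center = spec.center
    body = _ellipse_mask(shape, center, spec.body_semiaxes)
    inner_axes = (
        spec.body_semiaxes[0] - spec.sat_thickness,
        spec.body_semiaxes[1] - spec.sat_thickness,
    )
    if min(inner_axes) <= 0:
        raise ValueError("sat_thickness too large for the body ellipse")
    cavity = _ellipse_mask(shape, center, inner_axes)
    ring = body & ~cavity

    labels = np.full(shape, AIR, dtype=np.int8)
    labels[cavity] = LEAN

    if spec.dsat is not None:
        fascia_axes = (
            spec.body_semiaxes[0] - spec.fascia_offset,
            spec.body_semiaxes[1] - spec.fascia_offset,
        )
        fascia = _ellipse_mask(shape, center, fascia_axes)
        labels[ring & fascia] = DSAT
        labels[ring & ~fascia] = SSAT
    else:
        labels[ring] = SAT

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    vc = (center[0] + spec.visceral_offset[0], center[1] + spec.visceral_offset[1])
    disk = ((rr - vc[0]) ** 2 + (cc - vc[1]) ** 2 <= spec.visceral_radius ** 2)
    if np.any(disk & ~cavity):
        raise ValueError("visceral disk extends outside the abdominal cavity")

    cavity_bottom = center[0] + inner_axes[0]
    spine = (
        cavity
        & (np.abs(cc - center[1]) <= spec.spine_halfwidth)
        & (rr >= cavity_bottom - spec.spine_height)
    )
    if np.any(disk & spine):
        raise ValueError("visceral disk overlaps the spine wedge")
    labels[disk] = VAT
    labels[spine] = SPINE

    ff = np.zeros(shape)
    ndb = np.zeros(shape)
    nmidb = np.zeros(shape)
    r2s = np.zeros(shape)
    for label, region in _region_values(spec).items():
        sel = labels == label
        ff[sel] = region.fat_fraction
        ndb[sel] = region.ndb
        nmidb[sel] = region.nmidb
        r2s[sel] = region.r2star

    x = (cc - center[1]) / (shape[1] / 2.0)
    y = (rr - center[0]) / (shape[0] / 2.0)
    c0, cx, cy, cxx, cxy, cyy = spec.field_map_poly_hz
    psi = c0 + cx * x + cy * y + cxx * x**2 + cxy * x * y + cyy * y**2
    psi = np.where(labels != AIR, psi, 0.0)

    inside = labels != AIR
    water = np.where(inside, spec.signal_amplitude * (1.0 - ff), 0.0)
    fat = np.where(inside, spec.signal_amplitude * ff, 0.0)
    return GroundTruth(labels, ff, ndb, nmidb, psi, r2s, water, fat, spec)


def synthesize_echoes(
    truth: GroundTruth, acq: AcquisitionSpec, model: FatModelSpec
) -> np.ndarray:
    """Noiseless complex echo images (echo, rows, cols) from truth maps."""
    t = acq.echo_times
    p_f, p_ndb, p_nmidb = basis_coefficients(t, model, include_constant_ea=False)
    ndb = truth.ndb
    nmidb = truth.nmidb
    # sum(alpha) = 25 + 6(cl-4) - 2 ndb + ... evaluated termwise for generality
    alpha_sum = (
        25.0 + model.methylene_constant
        + 2.0 * ndb + 2.0 * nmidb + 4.0 * (ndb - nmidb)
        - 8.0 * ndb + 2.0 * nmidb
    )
    inside = truth.body
    inv_sum = np.where(inside, 1.0 / np.where(inside, alpha_sum, 1.0), 0.0)
    shape = truth.labels.shape
    out = np.zeros((acq.n_echoes,) + shape, dtype=complex)
    psi_term = 2j * np.pi * truth.psi_hz - truth.r2star
    for k in range(acq.n_echoes):
        fat_shape = truth.fat * inv_sum * (
            p_f[k] + ndb * p_ndb[k] + nmidb * p_nmidb[k]
        )
        out[k] = (truth.water + fat_shape) * np.exp(psi_term * t[k])
        out[k][~inside] = 0.0
    return out


def generate_phantom(
    spec: PhantomSpec,
    acq: AcquisitionSpec,
    model: FatModelSpec,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one noisy multi-echo phantom slice.

    Returns ``(echoes, truth)`` where ``echoes`` is complex with shape
    (n_echoes, rows, cols).  Noise is i.i.d. complex Gaussian with sigma =
    peak magnitude / snr per real channel, drawn from ``seed``; with
    ``spec.snr=None`` the output is noiseless and seed-independent.
    """
    truth = build_truth(spec)
    echoes = synthesize_echoes(truth, acq, model)
    if spec.snr is not None:
        rng = np.random.default_rng(seed)
        sigma = float(np.max(np.abs(echoes))) / spec.snr
        noise = rng.standard_normal(echoes.shape) + 1j * rng.standard_normal(echoes.shape)
        echoes = echoes + sigma * noise
    return echoes, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class DepotDistribution:
    """Group-level distribution of one depot's (ndb, nmidb).

    Independent normals matched by median (= mean) and interquartile range
    (sigma = IQR / 1.349), rejection-truncated to the valid region
    0 <= nmidb <= ndb with non-negative resonance amplitudes.
    """

    ndb_median: float
    ndb_iqr: float
    nmidb_median: float
    nmidb_iqr: float

    def __post_init__(self) -> None:
        if self.ndb_iqr < 0 or self.nmidb_iqr < 0:
            raise ValueError("IQRs must be non-negative")
        if self.ndb_median < 0 or self.nmidb_median < 0:
            raise ValueError("medians must be non-negative")

    def draw(self, rng: np.random.Generator, max_ndb: float = 9.0) -> tuple[float, float]:
        s_ndb = self.ndb_iqr / 1.349
        s_nmidb = self.nmidb_iqr / 1.349
        for _ in range(10_000):
            ndb = rng.normal(self.ndb_median, s_ndb) if s_ndb > 0 else self.ndb_median
            nmidb = (
                rng.normal(self.nmidb_median, s_nmidb)
                if s_nmidb > 0 else self.nmidb_median
            )
            if 0.0 <= nmidb <= ndb <= max_ndb:
                return float(ndb), float(nmidb)
        raise ValueError("could not draw a valid (ndb, nmidb) pair")


# Reference two-group depot distributions (medians and IQR widths of the
# study the synthetic cohorts emulate).  Group A is the larger group (n=23).
_GROUP_A = {
    "sat": DepotDistribution(2.56, 0.11, 0.48, 0.13),
    "vat": DepotDistribution(2.49, 0.19, 0.39, 0.11),
    "dsat": DepotDistribution(2.56, 0.14, 0.44, 0.11),
    "ssat": DepotDistribution(2.64, 0.19, 0.54, 0.10),
}
_GROUP_B = {
    "sat": DepotDistribution(2.24, 0.25, 0.26, 0.13),
    "vat": DepotDistribution(2.20, 0.18, 0.22, 0.07),
    "dsat": DepotDistribution(2.14, 0.23, 0.22, 0.07),
    "ssat": DepotDistribution(2.27, 0.18, 0.31, 0.18),
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with per-group, per-depot FAC distributions."""

    group_a: str = "iraqi"
    group_b: str = "swedish"
    n_a: int = 23
    n_b: int = 15
    distributions_a: dict = field(default_factory=lambda: dict(_GROUP_A))
    distributions_b: dict = field(default_factory=lambda: dict(_GROUP_B))

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("group sizes must be at least 2")
        if set(self.distributions_a) != set(self.distributions_b):
            raise ValueError("both groups must define the same depots")
        for dists in (self.distributions_a, self.distributions_b):
            for depot, d in dists.items():
                if not isinstance(d, DepotDistribution):
                    raise ValueError(f"distribution for {depot!r} has wrong type")

    @property
    def depots(self) -> tuple[str, ...]:
        return tuple(self.distributions_a)


def default_cohort_spec() -> CohortSpec:
    return CohortSpec()


def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(index))))


@dataclass(frozen=True)
class SubjectRecord:
    subject: str
    group: str
    depot_values: dict  # depot -> (ndb, nmidb)


def draw_cohort_truth(cohort: CohortSpec, master_seed: int) -> list[SubjectRecord]:
    """Per-subject true depot-level (ndb, nmidb) draws, deterministic in seed."""
    records: list[SubjectRecord] = []
    index = 0
    for group, n, dists in (
        (cohort.group_a, cohort.n_a, cohort.distributions_a),
        (cohort.group_b, cohort.n_b, cohort.distributions_b),
    ):
        for i in range(n):
            rng = _subject_rng(master_seed, index)
            values = {depot: dists[depot].draw(rng) for depot in cohort.depots}
            records.append(SubjectRecord(f"{group}_{i + 1:02d}", group, values))
            index += 1
    return records


def cohort_truth_frame(records: list[SubjectRecord]):
    """Tidy per-subject, per-depot truth table with derived fractions."""
    import pandas as pd

    rows = []
    for rec in records:
        for depot, (ndb, nmidb) in rec.depot_values.items():
            frac = fractions_from_double_bonds(ndb, nmidb)
            rows.append(
                {
                    "subject": rec.subject,
                    "group": rec.group,
                    "depot": depot,
                    "ndb": ndb,
                    "nmidb": nmidb,
                    "fsfa": float(frac.fsfa),
                    "fmufa": float(frac.fmufa),
                    "fpufa": float(frac.fpufa),
                }
            )
    return pd.DataFrame(rows)


def subject_phantom_spec(
    template: PhantomSpec, record: SubjectRecord
) -> PhantomSpec:
    """Instantiate the phantom template with one subject's depot truth."""
    values = record.depot_values
    updates: dict = {}
    sat_ndb, sat_nmidb = values.get("sat", (template.sat.ndb, template.sat.nmidb))
    updates["sat"] = replace(template.sat, ndb=sat_ndb, nmidb=sat_nmidb)
    if "vat" in values:
        updates["vat"] = replace(template.vat, ndb=values["vat"][0], nmidb=values["vat"][1])
    if "dsat" in values and "ssat" in values:
        base_d = template.dsat or template.sat
        base_s = template.ssat or template.sat
        updates["dsat"] = replace(base_d, ndb=values["dsat"][0], nmidb=values["dsat"][1])
        updates["ssat"] = replace(base_s, ndb=values["ssat"][0], nmidb=values["ssat"][1])
    return replace(template, **updates)


def simulate_cohort(
    cohort: CohortSpec,
    template: PhantomSpec,
    acq: AcquisitionSpec,
    model: FatModelSpec,
    master_seed: int,
) -> Iterator[tuple[SubjectRecord, np.ndarray, GroundTruth]]:
    """Yield (record, echoes, truth) per subject, deterministic in the seed.

    Subject substreams are derived by integer counter from the master seed,
    so regenerating with the same seed reproduces the cohort bit for bit.
    """
    records = draw_cohort_truth(cohort, master_seed)
    for index, record in enumerate(records):
        spec_i = subject_phantom_spec(template, record)
        noise_seed = np.random.SeedSequence((int(master_seed), int(index), 1))
        echoes, truth = generate_phantom(spec_i, acq, model, seed=noise_seed)
        yield record, echoes, truth
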