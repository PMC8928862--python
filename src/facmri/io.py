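"""File formats, configuration and the end-to-end pipeline.

Raster data travel as NIfTI: complex echo series are stored as a 5-D
volume (row, col, slice, echo, real/imag) with a JSON sidecar carrying the
echo times, and every parameter/FAC map is one volume sharing the input
affine.  Tabular outputs are CSV.  Every artifact embeds a SHA-256 hash of
the configuration that produced it, so provenance is reconstructible from
the outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import segmentation as seg
from .maps import FACMaps, ParameterMaps, derive_fac_maps
from .recon import FitConfig, fit_image
from .spectral import AcquisitionSpec, FatModelSpec
from .stats import depot_comparison_table
from .synth import CohortSpec, DepotDistribution, PhantomSpec, RegionFat, simulate_cohort

__all__ = [
    "EchoSeries",
    "read_echo_series",
    "write_echo_series",
    "write_parameter_maps",
    "write_fac_maps",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "run_pipeline",
]

log = logging.getLogger("facmri")


@dataclass
class EchoSeries:
    """Complex multi-echo image series with echo-time metadata.

    ``data`` has shape (n_echoes, n_slices, rows, cols); ``echo_times_s``
    has one entry per echo; ``affine`` is the NIfTI voxel-to-world map.
    """

    data: np.ndarray
    echo_times_s: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim == 3:  # single slice convenience
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError("data must be (echo, slice, row, col)")
        self.echo_times_s = np.asarray(self.echo_times_s, dtype=float)
        if self.echo_times_s.shape != (self.data.shape[0],):
            raise ValueError(
                f"{self.echo_times_s.size} echo times for {self.data.shape[0]} volumes"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("echo data holds non-finite values")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_echo_series(path, series: EchoSeries, extra_sidecar: dict | None = None) -> Path:
    """Write an echo series as NIfTI + JSON sidecar; returns the image path."""
    path = Path(path)
    # (echo, slice, row, col) -> (row, col, slice, echo, 2)
    stacked = np.stack([series.data.real, series.data.imag], axis=-1)
    vol = np.transpose(stacked, (2, 3, 1, 0, 4))
    img = nib.Nifti1Image(vol.astype(np.float64), series.affine)
    nib.save(img, str(path))
    sidecar = {
        "echo_times_s": [float(t) for t in series.echo_times_s],
        "n_echoes": series.n_echoes,
        "complex_layout": "last axis = (real, imag)",
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_echo_series(path) -> EchoSeries:
    """Read an echo series written by :func:`write_echo_series`.

    The echo count is cross-checked against the sidecar; missing sidecars,
    count mismatches and non-finite data raise ``ValueError``.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ValueError(f"missing echo-time sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 5 or vol.shape[-1] != 2:
        raise ValueError("expected a 5-D (row,col,slice,echo,2) volume")
    data = np.transpose(vol[..., 0] + 1j * vol[..., 1], (3, 2, 0, 1))
    times = np.asarray(sidecar["echo_times_s"], dtype=float)
    if times.size != data.shape[0]:
        raise ValueError(
            f"sidecar lists {times.size} echo times for {data.shape[0]} volumes"
        )
    return EchoSeries(data=data, echo_times_s=times, affine=img.affine)


def _write_map(path: Path, array: np.ndarray, affine: np.ndarray) -> None:
    arr = np.asarray(array, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_parameter_maps(outdir, pmaps: ParameterMaps, sidecar: dict | None = None) -> None:
    """One NIfTI per fitted parameter plus a validity mask and sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("w_mag", "f_mag", "ndb", "nmidb", "psi_hz", "r2star", "residual_norm"):
        _write_map(outdir / f"{name}.nii.gz", getattr(pmaps, name), pmaps.affine)
    _write_map(outdir / "valid.nii.gz", pmaps.valid.astype(float), pmaps.affine)
    if sidecar is not None:
        (outdir / "fit_config.json").write_text(json.dumps(sidecar, indent=1))


def write_fac_maps(outdir, fac: FACMaps, sidecar: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("fsfa", "fmufa", "fpufa", "fat_fraction", "t2star_s"):
        _write_map(outdir / f"{name}.nii.gz", getattr(fac, name), fac.affine)
    _write_map(outdir / "fac_valid.nii.gz", fac.valid.astype(float), fac.affine)
    if sidecar is not None:
        (outdir / "fac_config.json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# configuration


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _build(cls, mapping: dict, section: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")
    converted = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        converted[key] = value
    try:
        return cls(**converted)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section!r} section: {exc}") from exc


@dataclass(frozen=True)
class SegmentationConfig:
    growth_threshold: float = 0.5
    ff_min: float = 0.9
    ff_max: float = 1.1
    t2star_min_s: float = 0.020
    split_sat: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end pipeline configuration."""

    acquisition: AcquisitionSpec = AcquisitionSpec()
    model: FatModelSpec = FatModelSpec()
    fit: FitConfig = FitConfig()
    phantom: PhantomSpec = PhantomSpec()
    cohort: CohortSpec = CohortSpec()
    segmentation: SegmentationConfig = SegmentationConfig()
    seed: int = 0
    log_level: str = "INFO"


_REGION_KEYS = ("sat", "vat", "lean", "dsat", "ssat")


def _phantom_from_mapping(mapping: dict) -> PhantomSpec:
    mapping = dict(mapping or {})
    for key in _REGION_KEYS:
        if key in mapping and isinstance(mapping[key], dict):
            mapping[key] = _build(RegionFat, mapping[key], f"phantom.{key}")
    return _build(PhantomSpec, mapping, "phantom")


def _cohort_from_mapping(mapping: dict) -> CohortSpec:
    mapping = dict(mapping or {})
    for key in ("distributions_a", "distributions_b"):
        if key in mapping:
            mapping[key] = {
                depot: _build(DepotDistribution, d, f"cohort.{key}.{depot}")
                if isinstance(d, dict) else d
                for depot, d in mapping[key].items()
            }
    return _build(CohortSpec, mapping, "cohort")


def load_config(source) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a mapping or YAML/JSON file.

    Unknown keys anywhere are rejected before any computation runs.
    """
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as handle:
            source = yaml.safe_load(handle) or {}
    if not isinstance(source, dict):
        raise ConfigError("configuration root must be a mapping")
    known = {
        "acquisition", "model", "fit", "phantom", "cohort",
        "segmentation", "seed", "log_level",
    }
    unknown = set(source) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    return PipelineConfig(
        acquisition=_build(AcquisitionSpec, source.get("acquisition"), "acquisition"),
        model=_build(FatModelSpec, source.get("model"), "model"),
        fit=_build(FitConfig, source.get("fit"), "fit"),
        phantom=_phantom_from_mapping(source.get("phantom")),
        cohort=_cohort_from_mapping(source.get("cohort")),
        segmentation=_build(SegmentationConfig, source.get("segmentation"), "segmentation"),
        seed=int(source.get("seed", 0)),
        log_level=str(source.get("log_level", "INFO")),
    )


def _config_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _config_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _config_dict(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_config_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _analyse_subject(record, echoes, truth, cfg: PipelineConfig):
    """Fit one subject's slice and summarise every depot ROI."""
    from .maps import t2star_map

    pmaps = fit_image(echoes, cfg.acquisition, cfg.model, cfg.fit)
    fac = derive_fac_maps(pmaps)
    ff = fac.fat_fraction
    t2s = fac.t2star_s
    scfg = cfg.segmentation

    sat = seg.region_grow_sat(
        np.where(fac.valid, ff, np.nan), truth.sat_seed(), scfg.growth_threshold
    )
    vat = seg.delineate_vat(truth.cavity_polygon(), sat, ff)
    masks = {"sat": sat, "vat": vat}
    if scfg.split_sat:
        dsat, ssat = seg.split_sat_depots(sat, truth.fascia_polyline())
        masks["dsat"] = dsat
        masks["ssat"] = ssat

    rows = []
    for depot, mask in masks.items():
        roi = seg.refine_roi(
            mask, ff, t2s,
            ff_min=scfg.ff_min, ff_max=scfg.ff_max, t2star_min_s=scfg.t2star_min_s,
        )
        if not roi.any():
            log.warning("subject %s: empty ROI for depot %s", record.subject, depot)
            continue
        summary = seg.depot_mean_fac(fac, roi, pmaps)
        rows.append(
            {
                "subject": record.subject,
                "group": record.group,
                "depot": depot,
                "fsfa": summary.fsfa,
                "fmufa": summary.fmufa,
                "fpufa": summary.fpufa,
                "ndb": summary.ndb,
                "nmidb": summary.nmidb,
                "n_voxels": summary.n_voxels,
            }
        )
    return rows


def _write_csv(path: Path, frame: pd.DataFrame, chash: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# facmri config_hash={chash}\n")
        frame.to_csv(handle, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate a cohort, fit, segment, summarise and compare; write artifacts.

    Stages: simulate -> fit -> FAC maps -> masks -> ROI refinement -> depot
    means -> subject table -> comparison table.  Reruns with the same
    configuration are bit-identical.  Returns the output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    chash = config_hash(config)
    log.info("pipeline start (config hash %s)", chash)

    rows: list[dict] = []
    stage = "simulate"
    try:
        for record, echoes, truth in simulate_cohort(
            config.cohort, config.phantom, config.acquisition, config.model,
            config.seed,
        ):
            stage = f"analyse:{record.subject}"
            log.info("fitting subject %s", record.subject)
            rows.extend(_analyse_subject(record, echoes, truth, config))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if not rows:
        raise StageError("pipeline stage 'summarise' failed: no depot summaries")
    subject_table = pd.DataFrame(rows)
    subject_path = outdir / "subject_depot_table.csv"
    _write_csv(subject_path, subject_table, chash)

    stage = "compare"
    try:
        comparisons = depot_comparison_table(
            subject_table,
            group_order=(config.cohort.group_a, config.cohort.group_b),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"pipeline stage 'compare' failed: {exc}") from exc
    comparison_path = outdir / "comparison_table.csv"
    _write_csv(comparison_path, comparisons, chash)

    manifest = {
        "config_hash": chash,
        "config": _config_dict(config),
        "subjects": int(subject_table["subject"].nunique()),
        "outputs": [subject_path.name, comparison_path.name],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline done: %d subjects", manifest["subjects"])
    return {
        "subject_table": subject_path,
        "comparison_table": comparison_path,
        "manifest": outdir / "manifest.json",
    }
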