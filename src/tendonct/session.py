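"""Run configuration, volume I/O, report assembly and the demo pipeline.

A run is a pure function of its :class:`RunConfig` (profile, phantom spec,
sub-volume plan, seed): two runs with the same config produce byte-identical
reports. One gray export window per instrument profile is applied to every
volume written in a run and recorded in the provenance, so all volumes of a
run share one gray-scale interval.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ValidationError
from .morphometry import AreaProfile
from .phantom import PhantomSpec
from .quality import MetricSummary, QualityResult, summarize
from .volume import VolumeStack

log = logging.getLogger("tendonct")

#: Instrument profiles: the two optical microscope setups coupling the
#: scintillator to the camera. HNAM (4x) needs a 1-voxel Gaussian prefilter
#: before thresholding; HRM (20x) does not (the same threshold is found with
#: and without filtering).
PROFILES: dict[str, dict] = {
    "HNAM": {"voxel_size_um": 1.63, "energy_kev": 15.0, "prefilter_sigma": 1.0},
    "HRM": {"voxel_size_um": 0.33, "energy_kev": 15.0, "prefilter_sigma": None},
}


@dataclass
class RunConfig:
    """Effective configuration of one analysis run.

    ``profile`` presets voxel size, energy and the prefilter policy;
    explicitly set fields override the preset. The config round-trips
    losslessly through JSON.
    """

    profile: str = "HNAM"
    voxel_size_um: float | None = None
    energy_kev: float | None = None
    prefilter_sigma: float | None = "__profile__"  # type: ignore[assignment]
    seed: int = 0
    phantom: dict | None = None
    subvolume_count: int = 3
    subvolume_size: int = 64
    subvolume_stride: int = 64
    gray_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES and self.profile != "custom":
            raise ValidationError(
                f"profile must be one of {sorted(PROFILES)} or 'custom', "
                f"got {self.profile!r}"
            )
        preset = PROFILES.get(self.profile, {})
        if self.voxel_size_um is None:
            self.voxel_size_um = preset.get("voxel_size_um")
        if self.energy_kev is None:
            self.energy_kev = preset.get("energy_kev")
        if self.prefilter_sigma == "__profile__":
            self.prefilter_sigma = preset.get("prefilter_sigma")
        if self.voxel_size_um is None or self.energy_kev is None:
            raise ValidationError(
                "custom profile requires explicit voxel_size_um and energy_kev"
            )
        if self.gray_window is not None:
            lo, hi = self.gray_window
            if not hi > lo:
                raise ValidationError(f"gray_window must satisfy hi > lo, got {(lo, hi)}")
            self.gray_window = (float(lo), float(hi))

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "voxel_size_um": self.voxel_size_um,
            "energy_kev": self.energy_kev,
            "prefilter_sigma": self.prefilter_sigma,
            "seed": self.seed,
            "phantom": self.phantom,
            "subvolume_count": self.subvolume_count,
            "subvolume_size": self.subvolume_size,
            "subvolume_stride": self.subvolume_stride,
            "gray_window": list(self.gray_window) if self.gray_window else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("gray_window"):
            d["gray_window"] = tuple(d["gray_window"])
        if "prefilter_sigma" not in d:
            d["prefilter_sigma"] = "__profile__"
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Assembled per-sub-volume rows plus per-metric summaries."""

    rows: list[QualityResult]
    summaries: dict[str, MetricSummary]
    area: AreaProfile | None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Volume I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(
    volume: VolumeStack,
    path: str | Path,
    gray_window: tuple[float, float] | None = None,
) -> Path:
    """Write a volume as a multi-page TIFF with a JSON sidecar.

    With no window the float data are stored as 32-bit float pages; with a
    window the data are clipped and quantized to 16-bit over [lo, hi], and
    the window is recorded in the sidecar so reading restores the floats to
    within one quantization step.
    """
    path = Path(path)
    sidecar: dict = {
        "voxel_size_um": volume.voxel_size,
        "metadata": _jsonable(volume.metadata),
    }
    if gray_window is None:
        tifffile.imwrite(path, volume.data.astype(np.float32))
    else:
        lo, hi = gray_window
        if not hi > lo:
            raise ValidationError(f"gray window must satisfy hi > lo, got {(lo, hi)}")
        scaled = np.clip((volume.data - lo) / (hi - lo), 0.0, 1.0)
        tifffile.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
        sidecar["gray_window"] = [lo, hi]
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    log.info("wrote volume %s shape=%s voxel=%g µm", path, volume.shape,
             volume.voxel_size)
    return path


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VolumeStack:
    """Read a multi-page TIFF volume; voxel size from the JSON sidecar or,
    if the sidecar is absent, from the ``voxel_size_um`` argument.

    Integer pages written with a gray window are mapped back to floats over
    the recorded window; floats are returned unchanged.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types on bad input
        raise ValidationError(f"cannot read {path} as TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(
            f"{path}: pages do not form a 3D stack (mixed shapes?), got "
            f"ndim={data.ndim}"
        )
    sidecar = _sidecar_path(path)
    meta: dict = {}
    window = None
    if sidecar.exists():
        with open(sidecar) as fh:
            sc = json.load(fh)
        voxel_size_um = sc.get("voxel_size_um", voxel_size_um)
        meta = sc.get("metadata", {})
        window = sc.get("gray_window")
    if voxel_size_um is None:
        raise ValidationError(
            f"no voxel size: {sidecar} is missing and none was supplied"
        )
    out = data.astype(float)
    if window is not None and np.issubdtype(data.dtype, np.integer):
        lo, hi = window
        out = lo + out / 65535.0 * (hi - lo)
    log.info("read volume %s shape=%s voxel=%g µm", path, out.shape, voxel_size_um)
    return VolumeStack(out, float(voxel_size_um), meta)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

ROW_COLUMNS = [
    "content_label", "origin_z", "origin_y", "origin_x",
    "resolution_um", "fmcr", "uts_pct", "gse",
    "n_bins", "prefilter_sigma", "t_low", "t_high",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def assemble_report(
    rows: list[QualityResult],
    area: AreaProfile | None = None,
    provenance: dict | None = None,
) -> Report:
    """Build a report, recomputing the per-metric summaries from the rows."""
    summaries: dict[str, MetricSummary] = {}
    for metric in ("resolution_um", "fmcr", "uts_pct", "gse"):
        vals = [getattr(r, metric) for r in rows if getattr(r, metric) is not None]
        if len(vals) >= 2:
            summaries[metric] = summarize(vals)
    return Report(rows=rows, summaries=summaries, area=area,
                  provenance=provenance or {})


def write_report(report: Report, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as CSV rows, a JSON summary and a text digest.

    Field order is deterministic, so identical reports serialize to
    byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}")

    rows_df = pd.DataFrame([r.to_row() for r in report.rows])
    for col in ROW_COLUMNS:
        if col not in rows_df.columns:
            rows_df[col] = np.nan if len(rows_df) else pd.Series(dtype=float)
    rows_df = rows_df[ROW_COLUMNS]
    csv_path = out_dir / "quality_rows.csv"
    rows_df.to_csv(csv_path, index=False, float_format="%.9g")

    summary = {
        "metrics": {
            name: {"mean": s.mean, "sd": s.sd, "cv": s.cv, "n_repeats": s.n_repeats}
            for name, s in sorted(report.summaries.items())
        },
        "provenance": _jsonable(report.provenance),
    }
    if report.area is not None:
        summary["area"] = {
            "areas_mm2": report.area.areas_mm2.tolist(),
            "block_slices": report.area.block_slices,
            "z_starts": report.area.z_starts.tolist(),
            "mean_mm2": report.area.mean_mm2,
            "sd_mm2": report.area.sd_mm2,
        }
    json_path = out_dir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    lines = [f"tendonct {__version__} quality report",
             f"sub-volumes analyzed: {len(report.rows)}"]
    for name, s in sorted(report.summaries.items()):
        lines.append(
            f"{name}: mean={s.mean:.4g} sd={s.sd:.4g} cv={s.cv:.3f} n={s.n_repeats}"
        )
    if report.area is not None:
        lines.append(
            f"cross-sectional area: {report.area.mean_mm2:.4g} "
            f"± {report.area.sd_mm2:.4g} mm² over {len(report.area.areas_mm2)} blocks"
        )
    txt_path = out_dir / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "json": json_path, "txt": txt_path}


# ---------------------------------------------------------------------------
# Demo pipeline
# ---------------------------------------------------------------------------

def run_demo(config: RunConfig, out_dir: str | Path) -> Report:
    """Full synthetic pipeline: phantoms -> degradation -> sub-volumes ->
    four metrics -> summaries -> report files.

    Deterministic under the config seed; used both as the quick-start
    example and as the end-to-end determinism check.
    """
    from .morphometry import cross_section_area, extract_subvolumes
    from .phantom import (PhantomSpec, degrade, make_cylinder_phantom,
                          make_fat_cell_phantom, make_fiber_phantom)
    from .quality import analyze_subvolume

    vs = float(config.voxel_size_um)
    size = config.subvolume_size
    nz = (config.subvolume_count - 1) * config.subvolume_stride + size
    base = dict(config.phantom or {})
    base.setdefault("voxel_size", vs)
    base.setdefault("seed", config.seed)

    fiber_spec = PhantomSpec(**{**base, "shape": (nz, size, size)})
    log.info("demo: fiber phantom %s at %g µm", fiber_spec.shape, vs)
    fibers = make_fiber_phantom(fiber_spec)
    fibers = degrade(
        fibers,
        psf_sigma=fiber_spec.psf_sigma,
        noise_sigma=fiber_spec.noise_sigma,
        ring_amplitude=fiber_spec.ring_amplitude,
        seed=fiber_spec.seed,
    )
    subs = extract_subvolumes(
        fibers, config.subvolume_count, size, config.subvolume_stride,
        content_label="fibers",
    )
    rows = [analyze_subvolume(s, config.prefilter_sigma) for s in subs]

    fat_spec = PhantomSpec(**{**base, "shape": (size, size, size),
                              "seed": fiber_spec.seed + 1})
    fat = make_fat_cell_phantom(fat_spec)
    fat = degrade(
        fat,
        psf_sigma=fat_spec.psf_sigma,
        noise_sigma=fat_spec.noise_sigma,
        ring_amplitude=fat_spec.ring_amplitude,
        seed=fat_spec.seed,
    )
    fat_subs = extract_subvolumes(fat, 1, size, 1, content_label="fat_cells")
    rows.extend(analyze_subvolume(s) for s in fat_subs)

    tendon = make_cylinder_phantom(
        shape=(nz, size, size), voxel_size=vs,
        radius_um=0.35 * size * vs,
        inside_level=fiber_spec.fiber_level, outside_level=fiber_spec.matrix_level,
    )
    tendon = degrade(tendon, psf_sigma=fiber_spec.psf_sigma,
                     noise_sigma=fiber_spec.noise_sigma, ring_amplitude=0.0,
                     seed=fiber_spec.seed + 2)
    block = max(1, min(nz // 2, 100))
    area = cross_section_area(tendon, block=block, central_extent_um=nz * vs)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "tendonct_version": __version__,
        "seed": config.seed,
    }
    report = assemble_report(rows, area=area, provenance=provenance)
    write_report(report, out_dir)
    return report
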