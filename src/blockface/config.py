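"""Run configuration: YAML schema, validation and the end-to-end pipeline.

One structured config drives a whole simulate-then-analyze experiment; all
randomness flows from its single seed, and every run writes a provenance
record (config hash, seed, package version) next to its outputs so reports
are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError
from .imaging import ESBDetector, ScanGrid, render_bse_image
from .io import write_image, write_profile
from .materials import Material
from .mc import SimConfig
from .phantoms import DEFAULT_STAIN_DEPTHS, depth_series_phantom, vesicle_phantom
from .profiles import FIG6_CNR_THRESHOLD, extract_line_profile, region_visibility

log = logging.getLogger("blockface")


class MaterialCfg(BaseModel):
    elements: dict[str, float]
    density: float = Field(gt=0)


class PhantomCfg(BaseModel):
    kind: str = "depth_series"
    matrix: str = "epon"
    ga_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    stain_fraction: float = Field(default=0.03, ge=0.0, lt=1.0)
    lateral_size: float = 50.0
    spacing: float = 50.0
    depths: list[tuple[float, float]] | None = None
    burial_depth: float = 5.0  # vesicle only


class BeamCfg(BaseModel):
    energy_ev: float = 1500.0
    trajectories: int = 3000
    cutoff_ev: float = 50.0
    incidence_polar: float = 0.0


class DetectorCfg(BaseModel):
    grid_voltage: float = 0.0
    acceptance: tuple[float, float] = (0.0, math.pi / 2)


class ScanCfg(BaseModel):
    pixel_size: float = 3.0
    height: float = 60.0


class AnalysisCfg(BaseModel):
    cnr_threshold: float = FIG6_CNR_THRESHOLD
    min_region_pixels: int = 30
    guard_nm: float = 6.0
    shrink_nm: float = 3.0
    band_width_nm: float | None = None


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "scratch/run"
    materials: dict[str, MaterialCfg]
    phantom: PhantomCfg = PhantomCfg()
    beam: BeamCfg = BeamCfg()
    detector: DetectorCfg = DetectorCfg()
    scan: ScanCfg = ScanCfg()
    analysis: AnalysisCfg = AnalysisCfg()


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run config.

    Violations raise :class:`~blockface.errors.ConfigError` naming the
    offending key as a dotted path (e.g. ``materials.epon.density``).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"invalid config {path}: " + "; ".join(lines)
        ) from exc


def build_material(cfg: RunConfig, name: str) -> Material:
    if name not in cfg.materials:
        raise ConfigError(f"materials.{name}: not defined")
    mc = cfg.materials[name]
    return Material.from_symbols(name, mc.elements, mc.density)


def build_phantom(cfg: RunConfig):
    matrix = build_material(cfg, cfg.phantom.matrix)
    p = cfg.phantom
    if p.kind == "depth_series":
        depths = tuple(tuple(d) for d in p.depths) if p.depths else DEFAULT_STAIN_DEPTHS
        return depth_series_phantom(
            ga_fraction=p.ga_fraction,
            stain_fraction=p.stain_fraction,
            depths=depths,
            lateral_size=p.lateral_size,
            spacing=p.spacing,
            matrix=matrix,
        )
    if p.kind == "vesicle":
        return vesicle_phantom(
            ga_fraction=p.ga_fraction,
            stain_fraction=p.stain_fraction,
            burial_depth=p.burial_depth,
            matrix=matrix,
        )
    raise ConfigError(f"phantom.kind: unknown kind {p.kind!r}")


def sim_config(cfg: RunConfig) -> SimConfig:
    return SimConfig(
        beam_energy_ev=cfg.beam.energy_ev,
        trajectories_per_pixel=cfg.beam.trajectories,
        cutoff_ev=cfg.beam.cutoff_ev,
        seed=cfg.seed,
        incidence_polar=cfg.beam.incidence_polar,
    )


def run_experiment(config_path, output_dir=None, seed=None) -> dict:
    """Execute simulate -> analyze per config; idempotent for a fixed seed.

    Writes the rendered image (TIFF + sidecar), a band-averaged line profile
    (CSV), and a JSON report with the visibility analysis and a provenance
    record.  Returns the report dict.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    if seed is not None:
        cfg.seed = int(seed)
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = build_phantom(cfg)
    det = ESBDetector(cfg.detector.grid_voltage, tuple(cfg.detector.acceptance))
    scfg = sim_config(cfg)
    t0 = time.perf_counter()
    if cfg.phantom.kind == "depth_series":
        scan = phantom.default_scan(cfg.scan.pixel_size, cfg.scan.height)
    else:
        side = phantom.idx.shape[0] * phantom.voxel_size
        n = int(side / cfg.scan.pixel_size)
        scan = ScanGrid(n, n, cfg.scan.pixel_size, phantom.x0, phantom.y0)
    image = render_bse_image(phantom, scan, det, scfg)
    log.info(
        "rendered %dx%d pixels, %d traj/pixel in %.1f s",
        scan.ny,
        scan.nx,
        scfg.trajectories_per_pixel,
        time.perf_counter() - t0,
    )
    write_image(image, out / "image.tiff")
    profile = extract_line_profile(
        image, axis="x", band_width=cfg.analysis.band_width_nm
    )
    write_profile(profile, out / "profile.csv")
    report: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
            "seed": cfg.seed,
            "package": "blockface",
            "version": _version(),
        },
        "image": "image.tiff",
        "profile": "profile.csv",
        "mean_counts": float(image.counts.mean()),
    }
    if cfg.phantom.kind == "depth_series":
        vis = region_visibility(
            image,
            phantom.region_masks(scan, cfg.analysis.shrink_nm),
            phantom.background_mask(scan, cfg.analysis.guard_nm),
            threshold=cfg.analysis.cnr_threshold,
            min_pixels=cfg.analysis.min_region_pixels,
        )
        report["visibility"] = {
            "cnr": [round(c, 6) for c in vis.cnr],
            "threshold": vis.threshold,
            "visible": vis.visible,
            "visible_count": vis.visible_count,
            "z_resolution_bracket_nm": list(vis.bracket_nm) if vis.bracket_nm else None,
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("blockface")
    except Exception:
        return "unknown"
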