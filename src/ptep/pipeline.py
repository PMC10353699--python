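"""End-to-end pipeline runner: config validation, stage orchestration, provenance.

A single YAML/dict config with per-stage blocks drives
simulate → track → kinematics → accumulation → characterize.  All physical
constants (fluid density 997 kg/m³, viscosity 1e-3 Pa·s, fiber diameter
220 µm, g = 9.81 m/s²) are config defaults, never hard-coded in the
computation paths.  Outputs are deterministic for a fixed seed; the
provenance record carries the package version, the seed and a hash of the
resolved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .accumulation import (accumulation_area, accumulation_speed,
                           binarize_frame, concentration_profiles,
                           make_filter_windows, moving_average,
                           normalize_stack, rlowess_smooth, saturation_frame)
from .characterize import (characterization_report, classify_accumulation,
                           load_table1_fixture)
from .io import ImageStack, read_stack, write_stack
from .kinematics import summarize
from .scenarios import accumulation_scenario
from .specs import FluidSpec, ParticleSpec
from .track import track_stack

__all__ = ["PipelineConfig", "ConfigError", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or missing configuration field (named in the message)."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


_PHYSICS_DEFAULTS = {
    "fluid_density": 997.0,
    "fluid_viscosity": 1e-3,
    "characteristic_length_um": 220.0,
    "gravity": 9.81,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)
    input: dict[str, Any] = field(default_factory=dict)
    track: dict[str, Any] = field(default_factory=dict)
    kinematics: dict[str, Any] = field(default_factory=dict)
    accumulation: dict[str, Any] = field(default_factory=dict)
    physics: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "out_dir" not in raw:
            raise ConfigError("missing required field: out_dir")
        cfg = cls(out_dir=Path(raw["out_dir"]), seed=int(raw.get("seed", 0)),
                  simulate=raw.get("simulate", {}) or {},
                  input=raw.get("input", {}) or {},
                  track=raw.get("track", {}) or {},
                  kinematics=raw.get("kinematics", {}) or {},
                  accumulation=raw.get("accumulation", {}) or {},
                  physics={**_PHYSICS_DEFAULTS, **(raw.get("physics", {}) or {})})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, value in self.physics.items():
            if not (isinstance(value, (int, float)) and value > 0):
                raise ConfigError(f"physics constant {name} must be a positive "
                                  f"number, got {value!r}")
        if not self.simulate and not self.input:
            raise ConfigError("config needs either a 'simulate' block or an "
                              "'input' block")
        if self.input:
            for fld in ("stack", "frame_rate", "pixel_size_um"):
                if fld not in self.input:
                    raise ConfigError(f"input block missing required field: {fld}")
            if self.input["pixel_size_um"] <= 0:
                raise ConfigError("input field pixel_size_um must be > 0")

    def resolved(self) -> dict[str, Any]:
        d = {"out_dir": str(self.out_dir), "seed": self.seed,
             "simulate": self.simulate, "input": self.input,
             "track": self.track, "kinematics": self.kinematics,
             "accumulation": self.accumulation, "physics": self.physics}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; write intermediates and a metrics
    bundle under ``config.out_dir``; return the metrics dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict[str, Any] = {
        "provenance": {"ptep_version": __version__, "seed": config.seed,
                       "config_hash": config.config_hash()}}

    # --- simulate (optional) ---------------------------------------------
    truth = None
    if config.simulate:
        sim = dict(config.simulate)
        scenario = sim.pop("scenario", "accumulation")
        if scenario != "accumulation":
            raise PipelineStageError(
                "simulate", ValueError(f"unknown scenario {scenario!r}"))
        truth, stack, scene = _run_simulate(config, sim)
        tip_px = scene.fiber_tip_px
    else:
        stack = _run_load(config)
        tip_px = tuple(config.accumulation.get("tip_px", (0, 0)))

    # --- track + kinematics ----------------------------------------------
    trk = dict(config.track)
    radius_range = tuple(trk.pop("radius_range", (2, 6)))
    trajs = _run_track(stack, radius_range, trk)
    df = _trajectories_frame(trajs)
    df.to_csv(out / "tracks.csv", index=False)
    metrics["track"] = {"n_trajectories": len(trajs)}

    if trajs:
        kin = _run_kinematics(config, stack, trajs)
        metrics["kinematics"] = kin.to_dict()

    # --- accumulation -----------------------------------------------------
    acc_cfg = dict(config.accumulation)
    acc = _run_accumulation(stack, tip_px, acc_cfg, out)
    metrics["accumulation"] = acc

    # --- characterize -----------------------------------------------------
    records = load_table1_fixture()
    report = characterization_report(records)
    report["measured_label"] = classify_accumulation(acc["s_accum_per_s"])
    metrics["characterize"] = report

    (out / "metrics.json").write_text(
        json.dumps(metrics, sort_keys=True, indent=2))
    logger.info("pipeline finished; metrics in %s", out / "metrics.json")
    return metrics


@_stage("simulate")
def _run_simulate(config: PipelineConfig, sim: dict):
    truth, stack, scene = accumulation_scenario(seed=config.seed, **sim)
    return truth, stack, scene


@_stage("input")
def _run_load(config: PipelineConfig) -> ImageStack:
    return read_stack(config.input["stack"],
                      frame_rate=config.input["frame_rate"],
                      pixel_size_um=config.input["pixel_size_um"])


@_stage("track")
def _run_track(stack: ImageStack, radius_range, trk: dict):
    return track_stack(stack, radius_range, **trk)


@_stage("kinematics")
def _run_kinematics(config: PipelineConfig, stack: ImageStack, trajs):
    kin_cfg = dict(config.kinematics)
    particle = ParticleSpec(**kin_cfg.get(
        "particle", {"diameter_um": 2.0, "density": 1050.0}))
    fluid = FluidSpec(density=config.physics["fluid_density"],
                      viscosity=config.physics["fluid_viscosity"],
                      gravity=config.physics["gravity"])
    return summarize(trajs, stack.frame_rate, stack.pixel_size_um, particle,
                     fluid,
                     characteristic_length_um=config.physics[
                         "characteristic_length_um"])


@_stage("accumulation")
def _run_accumulation(stack: ImageStack, tip_px, acc_cfg: dict, out: Path):
    laser_on_s = float(acc_cfg.get("laser_on_s", 0.0))
    fit_duration_s = float(acc_cfg.get("fit_duration_s", 10.0))
    smooth_window = int(acc_cfg.get("smooth_window_frames",
                                    min(200, stack.n_frames)))
    offset_px = int(acc_cfg.get("grid_offset_px", 2))
    area_frame_s = acc_cfg.get("area_frame_s")

    norm = normalize_stack(stack)
    grid = make_filter_windows(tip_px, stack.shape, offset_px=offset_px)
    profile = concentration_profiles(norm, grid)
    profile.to_dataframe().to_csv(out / "concentration.csv", index=False)
    early = profile.slice(laser_on_s, laser_on_s + fit_duration_s)
    smooth_early = rlowess_smooth(
        early, window_frames=min(smooth_window, early.n_frames))
    s_accum = accumulation_speed(smooth_early, laser_on_s=laser_on_s,
                                 fit_duration_s=fit_duration_s)
    ma_window = min(int(acc_cfg.get("moving_average_frames", 300)),
                    profile.n_frames)
    sat = saturation_frame(moving_average(profile, ma_window))

    frame_idx = (stack.n_frames - 1 if area_frame_s is None
                 else min(int(round(area_frame_s * stack.frame_rate)),
                          stack.n_frames - 1))
    frame = norm.frames[frame_idx]
    binary = binarize_frame(frame, method="fixed",
                            threshold=float(acc_cfg.get("binarize_threshold",
                                                        128.0)))
    r0, c0 = grid.anchor
    block = grid.grid_n * grid.window_px
    pad = int(acc_cfg.get("roi_pad_px", 20))
    h, w = stack.shape
    roi = (max(r0 - pad, 0), min(r0 + block + pad, h),
           max(c0 - pad, 0), min(c0 + block + pad, w))
    tip_x = int(round(tip_px[0]))
    fiber_mask = np.zeros(stack.shape, dtype=bool)
    if acc_cfg.get("mask_fiber", True) and tip_x > 0:
        # fiber silhouette: everything left of the tip at fiber height
        half = int(acc_cfg.get("fiber_half_width_px", 23))
        ty = int(round(tip_px[1]))
        fiber_mask[max(ty - half, 0):min(ty + half + 1, h), :tip_x + 1] = True
    area = accumulation_area(binary, roi, stack.pixel_size_um,
                             fiber_mask=fiber_mask)
    import imageio.v3 as iio
    iio.imwrite(out / "binary_mask.png",
                (binary.astype(np.uint8) * 255))
    return {"s_accum_per_s": s_accum, "a_accum_um2": area,
            "saturation_frame": sat,
            "area_frame_index": int(frame_idx)}


def _trajectories_frame(trajs):
    import pandas as pd

    rows = []
    for t in trajs:
        for d in t.detections:
            rows.append((d.frame_index, t.particle_id, d.center[0],
                         d.center[1], d.radius))
    return pd.DataFrame(rows, columns=["frame", "particle_id", "x_px",
                                       "y_px", "radius_px"])
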