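"""File formats and experiment-level input/output.

Everything on disk is plain text: per-camera trajectory CSVs, a per-horse
JSON sidecar with the generating parameters and ground truth, groundline /
stride / trial CSV tables, and a JSON session report.  A YAML (or JSON)
experiment config describes N horses x a camera list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import TRUNK_KEYPOINTS, Groundline, TrajectorySet, as_jsonable, dump_json
from .session import (AnalysisOptions, ExperimentConfig, HorseData,
                      SessionData, analyze_recording, default_cameras,
                      default_horses, evaluate_session, simulate_session)
from .simulate import CameraModel, GaitParams
from .strides import split_trials, strides_to_dataframe

log = logging.getLogger("hoofline")

__all__ = [
    "ConfigError", "DataError", "config_from_dict", "config_to_dict",
    "load_config", "save_config", "save_session", "load_session",
    "run_simulate", "run_analyze", "compare_reports",
]


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


class DataError(RuntimeError):
    """Missing or malformed input data."""


# ---------------------------------------------------------------- config --

def config_to_dict(config: ExperimentConfig) -> dict:
    return as_jsonable({
        "seed": config.seed,
        "horses": [dataclasses.asdict(h) for h in config.horses],
        "cameras": [dataclasses.asdict(c) for c in config.cameras],
        "analysis": dataclasses.asdict(config.analysis),
    })


def config_from_dict(d: dict) -> ExperimentConfig:
    try:
        horses = [GaitParams(**h) for h in d.get("horses", [])]
        cameras = [CameraModel(**{**c, "image_size": tuple(c["image_size"])}
                               if "image_size" in c else c)
                   for c in d.get("cameras", [])]
        analysis = d.get("analysis", {})
        if "band" in analysis:
            analysis["band"] = tuple(analysis["band"])
        config = ExperimentConfig(horses=horses, cameras=cameras,
                                  analysis=AnalysisOptions(**analysis),
                                  seed=int(d.get("seed", 0)))
        config.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return config


def default_config(n_horses: int = 8, duration: float = 30.0,
                   seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(horses=default_horses(n_horses, duration=duration),
                            cameras=default_cameras(), seed=seed)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    text = path.read_text()
    try:
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(d)


# --------------------------------------------------------------- session --

def save_session(session: SessionData, outdir) -> None:
    """Write per-camera trajectory CSVs plus a truth JSON for every horse."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_json({"cameras": [dataclasses.asdict(c) for c in session.cameras]},
              outdir / "cameras.json")
    for i, horse in enumerate(session.horses):
        hdir = outdir / f"horse_{i:02d}"
        hdir.mkdir(exist_ok=True)
        for cam_id, traj in horse.trajectories.items():
            traj.to_csv(hdir / f"trajectory_cam{cam_id}.csv")
        dump_json({
            "params": dataclasses.asdict(horse.params),
            "fixed_groundlines": {k: {"angle_deg": a, "offset_px": o}
                                  for k, (a, o) in horse.fixed_groundlines.items()},
            "oracle": horse.oracle,
        }, hdir / "truth.json")
    log.info("wrote %d horses x %d cameras to %s",
             len(session.horses), len(session.cameras), outdir)


def load_session(indir) -> SessionData:
    indir = Path(indir)
    cam_file = indir / "cameras.json"
    if not cam_file.exists():
        raise DataError(f"missing file: {cam_file}")
    cams = [CameraModel(**{**c, "image_size": tuple(c["image_size"])})
            for c in json.loads(cam_file.read_text())["cameras"]]
    horses = []
    for hdir in sorted(indir.glob("horse_*")):
        truth_file = hdir / "truth.json"
        if not truth_file.exists():
            raise DataError(f"missing file: {truth_file}")
        truth = json.loads(truth_file.read_text())
        p = truth["params"]
        params = GaitParams(**p)
        trajs = {}
        for cam in cams:
            f = hdir / f"trajectory_cam{cam.camera_id}.csv"
            if not f.exists():
                raise DataError(f"missing file: {f}")
            trajs[cam.camera_id] = TrajectorySet.from_csv(f)
        fixed = {k: (v["angle_deg"], v["offset_px"])
                 for k, v in truth["fixed_groundlines"].items()}
        horses.append(HorseData(params=params, trajectories=trajs,
                                fixed_groundlines=fixed,
                                oracle=truth.get("oracle", {})))
    if not horses:
        raise DataError(f"no horse_* directories under {indir}")
    return SessionData(horses=horses, cameras=cams)


# ------------------------------------------------------------------ runs --

def run_simulate(config: ExperimentConfig, outdir) -> SessionData:
    session = simulate_session(config)
    save_session(session, outdir)
    save_config(config, Path(outdir) / "config.yaml")
    return session


def run_analyze(indir, outdir, opts: AnalysisOptions | None = None,
                groundline_mode: str = "dynamic", seed: int = 0) -> dict:
    """Load a simulated session from disk, analyse it, write tables + report.

    ``groundline_mode`` selects which variant's stride/trial tables are
    written per recording; the session report always contains both (the
    estimated-vs-fixed comparison needs them).
    """
    if groundline_mode not in ("dynamic", "fixed"):
        raise ConfigError(f"unknown groundline mode {groundline_mode!r}")
    session = load_session(indir)
    opts = opts or AnalysisOptions()
    cfgfile = Path(indir) / "config.yaml"
    if cfgfile.exists():
        config = load_config(cfgfile)
        config.analysis = opts
    else:
        config = ExperimentConfig(horses=[h.params for h in session.horses],
                                  cameras=session.cameras, analysis=opts,
                                  seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for i, horse in enumerate(session.horses):
        hdir = outdir / f"horse_{i:02d}"
        hdir.mkdir(exist_ok=True)
        for cam in session.cameras:
            traj = horse.trajectories[cam.camera_id]
            modes = ("dynamic",)
            fixed_gl = None
            if not cam.handheld and groundline_mode == "fixed":
                a, o = horse.fixed_groundlines[cam.camera_id]
                fixed_gl = Groundline.fixed(a, o, traj.n_frames)
                modes = ("dynamic", "fixed")
            try:
                res = analyze_recording(traj, horse.params.withers_height,
                                        opts, fixed_gl=fixed_gl, modes=modes)
            except (ValueError, RuntimeError) as exc:
                raise DataError(
                    f"horse {i}, camera {cam.camera_id}: {exc}") from exc
            mode = groundline_mode if groundline_mode in modes else "dynamic"
            res.groundline.to_csv(hdir / f"groundline_cam{cam.camera_id}.csv")
            stride_frames, trial_frames = [], []
            for kp in TRUNK_KEYPOINTS:
                recs = res.strides[(mode, kp)]
                stride_frames.append(strides_to_dataframe(recs, cam.camera_id))
                trials = split_trials(recs, opts.trial_len, cam.camera_id)
                trial_frames.append(pd.DataFrame([{
                    "trial_idx": t.index, "keypoint": kp,
                    "n_strides": t.n_strides, "maxdiff_mm": t.maxdiff,
                    "mindiff_mm": t.mindiff, "camera_id": t.camera_id,
                } for t in trials]))
            strides_df = pd.concat(stride_frames, ignore_index=True)
            strides_df.to_csv(hdir / f"strides_cam{cam.camera_id}.csv", index=False)
            pd.concat(trial_frames, ignore_index=True).to_csv(
                hdir / f"trials_cam{cam.camera_id}.csv", index=False)
            n_total = len(strides_df)
            n_valid = int(strides_df["valid"].sum())
            log.info("horse %d cam %s: %d frames, %d strides (%d valid, %d excluded)",
                     i, cam.camera_id, traj.n_frames, n_total, n_valid,
                     n_total - n_valid)

    report = evaluate_session(config, session=session)
    dump_json(report, outdir / "report.json")
    return report


# --------------------------------------------------------------- compare --

def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def compare_reports(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Metric-by-metric differences between two session reports.

    Both reports must share the same metric schema; a metric present in one
    but not the other is a schema mismatch and is reported as an error
    naming the missing keys.  Each row carries the n of the statistic's
    source sample where available.
    """
    fa = _flatten(report_a)
    fb = _flatten(report_b)
    only_a = sorted(set(fa) - set(fb))
    only_b = sorted(set(fb) - set(fa))
    if only_a or only_b:
        raise DataError("report schema mismatch; missing metrics: "
                        f"A-only={only_a[:5]} B-only={only_b[:5]}")
    rows = []
    for key in sorted(fa):
        group = key.rsplit(".", 1)[0]
        n_a = fa.get(f"{group}.n")
        n_b = fb.get(f"{group}.n")
        rows.append({"metric": key, "value_a": fa[key], "value_b": fb[key],
                     "diff": fa[key] - fb[key],
                     "n_a": n_a, "n_b": n_b})
    return pd.DataFrame(rows)
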