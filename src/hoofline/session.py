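"""Experiment configuration and the end-to-end analysis session.

A session is one simulated data-collection run: N horses, each recorded by
the default seven-camera rig (six stationary views at mixed heights and
obliquities plus one handheld side view), analysed three ways:

1. groundline angle error — per-frame dynamic estimate vs the fixed
   treadmill-marked line, pooled over all stationary recordings;
2. estimated-vs-fixed closure — per-stride Maxdiff/Mindiff computed with
   the dynamic groundline vs the fixed one on the same video;
3. handheld-vs-stationary — stride- and trial-level symmetry metrics from
   the handheld camera vs a stationary reference camera.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .agreement import agreement, match_strides
from .core import TRUNK_KEYPOINTS, Groundline, TrajectorySet
from .groundline import angle_error, detect_stance, estimate_groundline
from .simulate import (CameraModel, GaitParams, WorldTrack, corrupt, project,
                       simulate_gait, symmetry_oracle, true_groundline)
from .strides import StrideRecord, segment_strides, split_trials
from .vds import calibrate, compute_vds, estimate_stride_frequency, highpass, lowpass

__all__ = [
    "AnalysisOptions", "ExperimentConfig", "SessionData", "HorseData",
    "RecordingAnalysis", "default_cameras", "default_horses",
    "simulate_session", "analyze_recording", "evaluate_session",
]


@dataclass
class AnalysisOptions:
    """Tunable thresholds of the analysis pipeline (all config-exposed)."""

    v_thresh: float = 1.5          # px/frame, stance vertical-speed threshold
    d_thresh: float = 5.0          # px, stance distance-to-ground threshold
    min_stance: int = 3            # frames
    gap_close: int = 2             # frames of stance dropout to bridge
    smooth_frames: int = 5         # hoof-track smoothing for stance detection
    window: int = 15               # frames, groundline sliding window (~0.5 s)
    offset_track: int = 4          # frames; per-frame groundline offset tracking
    filter_order: int = 3
    smooth_hz: float | None = 6.0  # detector-jitter low-pass; None disables
    band: tuple[float, float] = (0.5, 2.5)   # stride-frequency search band, Hz
    min_prominence_frac: float = 0.2
    max_residual_frac: float = 0.2
    warmup_s: float | None = None   # None: one high-pass cutoff period per end
    min_coverage: float = 0.5
    trial_len: int = 17
    ci_level: float = 0.99
    reference_camera: str = "4"    # stationary partner of the handheld view


@dataclass
class ExperimentConfig:
    """N horses x camera list, with analysis options and a master seed."""

    horses: list[GaitParams]
    cameras: list[CameraModel]
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0

    def validate(self) -> None:
        ids = [c.camera_id for c in self.cameras]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate camera id(s): {dupes}")
        for h in self.horses:
            h.validate()
        for c in self.cameras:
            c.validate()


def default_cameras() -> list[CameraModel]:
    """The seven-camera treadmill rig used throughout.

    Six stationary views — an oblique front and an oblique rear view at
    50 degrees, three perpendicular right-side views at 50/100/160 cm
    height, one perpendicular left-side view — plus a handheld right-side
    camera at shoulder height with a ~1 Hz, 20 mm operator bounce.
    """
    return [
        CameraModel(camera_id="1", distance_from_midline=300, view_angle=50,
                    height=100, side="right", oblique="front"),
        CameraModel(camera_id="2", distance_from_midline=300, view_angle=90,
                    height=50, side="right"),
        CameraModel(camera_id="3", distance_from_midline=300, view_angle=90,
                    height=100, side="right"),
        CameraModel(camera_id="4", distance_from_midline=300, view_angle=90,
                    height=160, side="right"),
        CameraModel(camera_id="5", distance_from_midline=300, view_angle=50,
                    height=100, side="right", oblique="rear"),
        CameraModel(camera_id="6", distance_from_midline=250, view_angle=90,
                    height=100, side="left", focal_length=1250),
        CameraModel(camera_id="7", distance_from_midline=300, view_angle=90,
                    height=160, side="right", handheld=True,
                    bounce_amp=20.0, bounce_frequency=1.0),
    ]


def default_horses(n: int = 8, duration: float = 30.0,
                   noise_sigma: float = 1.0,
                   occlusion_rate: float = 0.001) -> list[GaitParams]:
    """A cohort of n horses spanning realistic treadmill-trot conditions.

    Withers heights span 154-168 cm and belt speeds 4.5-5.2 m/s (stride
    rate near 1.25 Hz); the cohort carries a spread of genuine asymmetry
    amplitudes (0-4 mm) so agreement statistics cover a range of true
    Maxdiff/Mindiff values, as an unscreened group of horses would.
    """
    if n < 1:
        raise ValueError("need at least one horse")
    g = lambda lo, hi: np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    heights = g(154.0, 168.0)
    speeds = g(4.5, 5.2)
    freqs = g(1.20, 1.30)
    asyms = g(0.0, 4.0)
    phases = g(0.0, np.pi / 2)
    return [GaitParams(stride_frequency=float(freqs[i]),
                       belt_speed=float(speeds[i]),
                       withers_height=float(heights[i]),
                       asym_amp=float(asyms[i]),
                       asym_phase=float(phases[i]),
                       duration=duration,
                       noise_sigma=noise_sigma,
                       occlusion_rate=occlusion_rate,
                       seed=i)
            for i in range(n)]


@dataclass
class HorseData:
    """One horse's simulated session: per-camera trajectories plus truth."""

    params: GaitParams
    trajectories: dict[str, TrajectorySet]
    fixed_groundlines: dict[str, tuple[float, float]]  # static cams only
    oracle: dict[str, dict] = field(default_factory=dict)


@dataclass
class SessionData:
    horses: list[HorseData]
    cameras: list[CameraModel]

    def camera(self, camera_id: str) -> CameraModel:
        for c in self.cameras:
            if c.camera_id == camera_id:
                return c
        raise KeyError(f"missing camera {camera_id!r} in session")


def _derived_seeds(master: int, count: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=count)]


def simulate_session(config: ExperimentConfig) -> SessionData:
    """Simulate every horse through every camera, deterministically.

    The master seed expands into independent per-horse/per-camera noise and
    bounce seeds, so identical configs give bit-identical trajectories.
    """
    config.validate()
    seeds = iter(_derived_seeds(config.seed, 2 * len(config.horses) * len(config.cameras)))
    horses: list[HorseData] = []
    for params in config.horses:
        world = simulate_gait(params)
        trajs: dict[str, TrajectorySet] = {}
        fixed: dict[str, tuple[float, float]] = {}
        for cam in config.cameras:
            cam_h = dataclasses.replace(cam, bounce_seed=next(seeds)) \
                if cam.handheld else cam
            traj = project(world, cam_h)
            traj = corrupt(traj, params.noise_sigma, params.occlusion_rate,
                           seed=next(seeds))
            if not cam.handheld:
                gl = true_groundline(world, cam_h)
                fixed[cam.camera_id] = gl.at(0)
            trajs[cam.camera_id] = traj
        oracle = {}
        for kp in TRUNK_KEYPOINTS:
            onsets, maxd, mind = symmetry_oracle(params, kp)
            oracle[kp] = {"onset_s": onsets.tolist(),
                          "maxdiff_mm": maxd.tolist(),
                          "mindiff_mm": mind.tolist()}
        horses.append(HorseData(params=params, trajectories=trajs,
                                fixed_groundlines=fixed, oracle=oracle))
    return SessionData(horses=horses, cameras=list(config.cameras))


@dataclass
class RecordingAnalysis:
    """Everything the pipeline derives from one camera's trajectory set."""

    stances: list
    groundline: Groundline                  # dynamic estimate
    f_est: float
    vds: dict[tuple[str, str], object]      # (mode, keypoint) -> VDSeries
    strides: dict[tuple[str, str], list[StrideRecord]]

    def valid_strides(self, mode: str, keypoint: str) -> list[StrideRecord]:
        return [s for s in self.strides[(mode, keypoint)] if s.valid]


def _limb_signal(traj: TrajectorySet) -> np.ndarray:
    for kp in ("lf_hoof", "rf_hoof", "lh_hoof", "rh_hoof"):
        if kp in traj.keypoints:
            xy, vis = traj.point(kp)
            y = xy[:, 1].copy()
            y[~vis] = np.nan
            if np.isfinite(y).mean() > 0.5:
                return y
    raise ValueError("no hoof keypoint with usable coverage for frequency estimation")


def analyze_recording(traj: TrajectorySet, withers_height: float,
                      opts: AnalysisOptions = AnalysisOptions(),
                      fixed_gl: Groundline | None = None,
                      modes: tuple[str, ...] = ("dynamic",),
                      keypoints: tuple[str, ...] = TRUNK_KEYPOINTS,
                      ) -> RecordingAnalysis:
    """Run the full pipeline on one recording.

    ``modes`` selects the groundline variant(s): "dynamic" (estimated per
    frame from hoof keypoints) and/or "fixed" (requires ``fixed_gl``, the
    treadmill-marked control).  Both variants share stance detection and
    the stride-frequency estimate, exactly as when the same video is
    processed twice.
    """
    kw = dict(v_thresh=opts.v_thresh, d_thresh=opts.d_thresh,
              min_stance=opts.min_stance, smooth_frames=opts.smooth_frames,
              gap_close=opts.gap_close)
    stances = detect_stance(traj, traj.fps, **kw)
    gl_dyn = estimate_groundline(traj, stances, window=opts.window,
                                 offset_track=opts.offset_track)
    # second pass: re-detect stance against the tracked line (sharper under
    # camera motion and oblique views), then re-fit the line
    stances = detect_stance(traj, traj.fps, reference=gl_dyn, **kw)
    gl_dyn = estimate_groundline(traj, stances, window=opts.window,
                                 offset_track=opts.offset_track)
    f_est = estimate_stride_frequency(_limb_signal(traj), traj.fps,
                                      band=opts.band)
    glines = {"dynamic": gl_dyn}
    if "fixed" in modes:
        if fixed_gl is None:
            raise ValueError("fixed mode requested but no fixed groundline given")
        glines["fixed"] = fixed_gl
    vds_out, strides_out = {}, {}
    for mode in modes:
        gl = glines[mode]
        for kp in keypoints:
            series = compute_vds(traj, gl, kp)
            series = calibrate(series, traj, gl, withers_height,
                               min_coverage=opts.min_coverage)
            series = highpass(series, f_est, order=opts.filter_order)
            if opts.smooth_hz is not None:
                series = lowpass(series, opts.smooth_hz, order=opts.filter_order)
            warmup = opts.warmup_s if opts.warmup_s is not None \
                else 1.0 / series.hp_cutoff_hz
            recs = segment_strides(traj, stances, series,
                                   min_prominence_frac=opts.min_prominence_frac,
                                   max_residual_frac=opts.max_residual_frac,
                                   warmup_s=warmup)
            vds_out[(mode, kp)] = series
            strides_out[(mode, kp)] = recs
    return RecordingAnalysis(stances=stances, groundline=gl_dyn, f_est=f_est,
                             vds=vds_out, strides=strides_out)


def _stats_dict(diffs: np.ndarray, ci_level: float) -> dict:
    return agreement(np.asarray(diffs, float), ci_level=ci_level).as_dict()


def evaluate_session(config: ExperimentConfig,
                     session: SessionData | None = None) -> dict:
    """Run the three agreement analyses on a (simulated) session.

    Returns a nested report dict: groundline angle statistics, pooled and
    per-keypoint estimated-vs-fixed stride agreement, stride-detection
    accounting against the theoretical stride count (duration x stride
    frequency, summed over recordings), and stride-/trial-level
    handheld-vs-stationary agreement.
    """
    config.validate()
    if session is None:
        session = simulate_session(config)
    opts = config.analysis
    static_ids = [c.camera_id for c in session.cameras if not c.handheld]
    handheld_ids = [c.camera_id for c in session.cameras if c.handheld]
    if handheld_ids and opts.reference_camera not in static_ids:
        raise ValueError(f"missing camera {opts.reference_camera!r} "
                         f"(stationary reference for the handheld comparison)")

    angle_errs: list[np.ndarray] = []
    ef_diffs = {("maxdiff", kp): [] for kp in TRUNK_KEYPOINTS}
    ef_diffs.update({("mindiff", kp): [] for kp in TRUNK_KEYPOINTS})
    accounting = {kp: {"theoretical": 0.0, "detected": 0, "excluded": 0}
                  for kp in TRUNK_KEYPOINTS}
    hh_stride = {(m, kp): [] for m in ("maxdiff", "mindiff")
                 for kp in TRUNK_KEYPOINTS}
    hh_trial = {(m, kp): [] for m in ("maxdiff", "mindiff")
                for kp in TRUNK_KEYPOINTS}

    for horse in session.horses:
        h = horse.params.withers_height
        analyses: dict[str, RecordingAnalysis] = {}
        for cam_id in static_ids:
            ang, off = horse.fixed_groundlines[cam_id]
            traj = horse.trajectories[cam_id]
            fixed = Groundline.fixed(ang, off, traj.n_frames)
            res = analyze_recording(traj, h, opts, fixed_gl=fixed,
                                    modes=("dynamic", "fixed"))
            analyses[cam_id] = res
            angle_errs.append(angle_error(res.groundline, fixed).errors)
            for kp in TRUNK_KEYPOINTS:
                dyn = res.strides[("dynamic", kp)]
                fix = res.strides[("fixed", kp)]
                for sd, sf in zip(dyn, fix):
                    if sd.valid and sf.valid:
                        ef_diffs[("maxdiff", kp)].append(sd.maxdiff - sf.maxdiff)
                        ef_diffs[("mindiff", kp)].append(sd.mindiff - sf.mindiff)
                acc = accounting[kp]
                acc["theoretical"] += horse.params.duration * res.f_est
                acc["detected"] += sum(s.valid for s in dyn)
                acc["excluded"] += sum(not s.valid for s in dyn)

        for hh_id in handheld_ids:
            res_h = analyze_recording(horse.trajectories[hh_id], h, opts)
            res_s = analyses[opts.reference_camera]
            for kp in TRUNK_KEYPOINTS:
                a = res_h.strides[("dynamic", kp)]
                b = res_s.strides[("dynamic", kp)]
                pairs = [(i, j) for i, j in match_strides(a, b)
                         if a[i].valid and b[j].valid]
                md = [(a[i].maxdiff, b[j].maxdiff) for i, j in pairs]
                nd = [(a[i].mindiff, b[j].mindiff) for i, j in pairs]
                hh_stride[("maxdiff", kp)].extend(x - y for x, y in md)
                hh_stride[("mindiff", kp)].extend(x - y for x, y in nd)
                L = opts.trial_len
                for i0 in range(0, len(pairs) - L + 1, L):
                    chunk_m = md[i0:i0 + L]
                    chunk_n = nd[i0:i0 + L]
                    hh_trial[("maxdiff", kp)].append(
                        float(np.mean([x for x, _ in chunk_m])
                              - np.mean([y for _, y in chunk_m])))
                    hh_trial[("mindiff", kp)].append(
                        float(np.mean([x for x, _ in chunk_n])
                              - np.mean([y for _, y in chunk_n])))

    report: dict = {"config": {
        "n_horses": len(session.horses),
        "cameras": [c.camera_id for c in session.cameras],
        "seed": config.seed,
    }}

    all_angle = np.concatenate(angle_errs) if angle_errs else np.empty(0)
    all_angle = all_angle[np.isfinite(all_angle)]
    report["groundline_angle"] = _stats_dict(all_angle, opts.ci_level) \
        if len(all_angle) >= 2 else {"n": int(len(all_angle))}

    ef = {"per_keypoint": {}}
    for metric in ("maxdiff", "mindiff"):
        pooled = []
        for kp in TRUNK_KEYPOINTS:
            d = ef_diffs[(metric, kp)]
            pooled.extend(d)
            if len(d) >= 2:
                ef["per_keypoint"].setdefault(kp, {})[metric] = \
                    _stats_dict(d, opts.ci_level)
        ef[metric] = _stats_dict(pooled, opts.ci_level) if len(pooled) >= 2 else {"n": len(pooled)}
    report["estimated_vs_fixed"] = ef

    acc_rep = {"per_keypoint": {}}
    tot_theo = tot_det = tot_exc = 0.0
    for kp, acc in accounting.items():
        theo = acc["theoretical"]
        rate = 1.0 - acc["detected"] / theo if theo > 0 else float("nan")
        acc_rep["per_keypoint"][kp] = {**acc, "failure_rate": rate}
        tot_theo += theo
        tot_det += acc["detected"]
        tot_exc += acc["excluded"]
    acc_rep.update(theoretical=tot_theo, detected=int(tot_det),
                   excluded=int(tot_exc),
                   failure_rate=(1.0 - tot_det / tot_theo) if tot_theo else float("nan"))
    report["stride_accounting"] = acc_rep

    if handheld_ids:
        hh = {}
        for level, store in (("stride", hh_stride), ("trial", hh_trial)):
            lev = {"per_keypoint": {}}
            for metric in ("maxdiff", "mindiff"):
                pooled = []
                for kp in TRUNK_KEYPOINTS:
                    d = store[(metric, kp)]
                    pooled.extend(d)
                    if len(d) >= 2:
                        lev["per_keypoint"].setdefault(kp, {})[metric] = \
                            _stats_dict(d, opts.ci_level)
                lev[metric] = _stats_dict(pooled, opts.ci_level) \
                    if len(pooled) >= 2 else {"n": len(pooled)}
            hh[level] = lev
        report["handheld_vs_stationary"] = hh
    return report
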