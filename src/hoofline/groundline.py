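"""Dynamic groundline estimation from hoof keypoints.

The ground reference for vertical displacement is an image-plane line.  It
can be estimated per frame from the hoof keypoints of stance-phase legs
("dynamic groundline"), or marked once and held constant ("fixed
groundline" control).  This module detects stance, fits the per-frame line
robustly, rectifies trajectories so the line is horizontal, and quantifies
the angle error between two groundlines.

Stance detection on a treadmill deserves a note: a stance hoof is *not*
stationary in the image — it translates with the belt — and under a
handheld camera every keypoint additionally moves with the operator.  Both
effects are removed by measuring each hoof's height relative to a per-frame
ground-level estimate (the median-filtered lowest hoof), which tracks both
the belt-invariant ground and any common-mode camera motion.  Stance is
then "near the ground and vertically at rest relative to it".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as _signal

from .core import (HOOF_KEYPOINTS, LEGS, Groundline, TrajectorySet,
                   height_above_line, line_from_slope_intercept)

__all__ = [
    "StanceEvent", "detect_stance", "estimate_groundline", "rectify",
    "angle_error", "AngleErrorSummary", "l1_line_fit",
]


@dataclass
class StanceEvent:
    """One maximal run of frames during which a hoof is on the ground."""

    leg: str
    start: int                 # first frame (inclusive)
    end: int                   # last frame (inclusive)
    pixel: tuple[float, float]  # representative (median) hoof pixel

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("stance event with end < start")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


def _interp_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs, edge-filled with nearest finite."""
    x = np.asarray(x, dtype=float).copy()
    ok = np.isfinite(x)
    if not ok.any():
        return x
    idx = np.arange(len(x))
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs of length <= max_gap that sit between True runs."""
    if max_gap <= 0 or not mask.any():
        return mask
    out = mask.copy()
    idx = np.flatnonzero(mask)
    gaps = np.diff(idx)
    for i, g in enumerate(gaps):
        if 1 < g <= max_gap + 1:
            out[idx[i] + 1:idx[i + 1]] = True
    return out


def _runs(mask: np.ndarray):
    """Yield (start, stop_exclusive) for each True run."""
    diff = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_stance(traj: TrajectorySet, fps: float | None = None, *,
                  v_thresh: float = 1.5, d_thresh: float = 5.0,
                  min_stance: int = 3, smooth_frames: int = 5,
                  ground_filter_frames: int = 5,
                  gap_close: int = 2,
                  reference: Groundline | None = None) -> list[StanceEvent]:
    """Detect stance-phase frame runs for every hoof keypoint present.

    Per leg, a frame is in stance when the hoof's smoothed vertical position
    is within ``d_thresh`` px of the per-frame ground-level estimate and its
    vertical speed relative to that estimate is below ``v_thresh`` px/frame.
    Runs shorter than ``min_stance`` frames are discarded; gaps up to
    ``gap_close`` frames inside a run (single-frame detection dropouts) are
    bridged first.  Returns an empty list when nothing qualifies.

    When a per-frame ``reference`` groundline is supplied (e.g. a
    first-pass estimate), hoof heights are measured against it directly,
    replacing the internal coarse line and camera-motion tracking — the
    second pass of an iterated detect/estimate cycle.
    """
    del fps  # thresholds are per-frame quantities; kept for signature clarity
    legs = [leg for leg in LEGS if HOOF_KEYPOINTS[leg] in traj.keypoints]
    if not legs:
        raise ValueError("trajectory has no hoof keypoints")

    uv, vis_all = {}, {}
    for leg in legs:
        xy, vis = traj.point(HOOF_KEYPOINTS[leg])
        filled = xy.copy()
        filled[~vis] = np.nan
        uv[leg] = np.column_stack([_interp_nan(filled[:, 0]),
                                   _interp_nan(filled[:, 1])])
        vis_all[leg] = vis

    if reference is not None:
        if len(reference) != traj.n_frames:
            raise ValueError("reference groundline frame count mismatch")
        d = {leg: height_above_line(reference.angle_deg, reference.offset_px,
                                    uv[leg]) for leg in legs}
        d_smooth = {leg: _moving_average(d[leg], smooth_frames) for leg in legs}
        ground = np.zeros(traj.n_frames)
    else:
        # a coarse static reference line through the per-frame lowest hoof
        # pixels makes "height" meaningful in oblique views, where the
        # ground trace is slanted in image coordinates.  Two robust-fit
        # iterations: first "lowest" by raw y, then by distance to the
        # first line.
        stack = np.stack([uv[leg] for leg in legs])          # (L, n, 2)
        coarse = None
        for _ in range(2):
            if coarse is None:
                pick = np.argmax(stack[:, :, 1], axis=0)
            else:
                a0, o0 = coarse
                pick = np.argmin(height_above_line(a0, o0, stack), axis=0)
            pts = stack[pick, np.arange(stack.shape[1])]
            step = max(1, len(pts) // 400)
            u, v = pts[::step, 0], pts[::step, 1]
            if np.ptp(u) < 50.0:  # degenerate abscissa spread: horizontal
                coarse = (0.0, float(np.quantile(v, 0.95)))
            else:
                coarse = line_from_slope_intercept(*l1_line_fit(u, v))
        d = {leg: height_above_line(coarse[0], coarse[1], uv[leg])
             for leg in legs}
        d_smooth = {leg: _moving_average(d[leg], smooth_frames) for leg in legs}

        # ground level in line-referenced coordinates: the lowest hoof,
        # median-filtered over brief suspension gaps; tracks common-mode
        # camera motion.  With a single hoof there is no common mode to
        # separate, so the reference stays the static line itself.
        if len(legs) >= 2:
            # unsmoothed heights: suspension excursions stay 1-2 frames
            # wide, so the short median filter rejects them while still
            # tracking a bouncing camera
            lowest = np.min(np.stack([d[leg] for leg in legs]), axis=0)
            ground = ndimage.median_filter(lowest,
                                           size=max(1, ground_filter_frames),
                                           mode="nearest")
        else:
            ground = np.zeros(traj.n_frames)

    events: list[StanceEvent] = []
    for leg in legs:
        xy, vis = traj.point(HOOF_KEYPOINTS[leg])
        rel_raw = d[leg] - ground
        rel = d_smooth[leg] - ground
        speed = np.abs(np.gradient(rel))
        mask = (np.abs(rel) <= d_thresh) & (speed <= v_thresh) & vis
        mask = _close_gaps(mask, gap_close)
        # the smoothed-speed criterion erodes stance edges by a frame or
        # two; grow each qualifying run back out along frames that stay
        # right at the ground level.  The growth threshold adapts to the
        # measured keypoint jitter so noisy edge frames are not dropped.
        runs = [(a, b) for a, b in _runs(mask) if b - a >= min_stance]
        grown = np.zeros_like(mask)
        in_run = np.zeros_like(mask)
        for a, b in runs:
            in_run[a:b] = True
        if in_run.sum() >= 4:
            steps = np.diff(rel_raw[in_run])
            steps = steps[np.isfinite(steps)]
            sigma_hat = 1.4826 * np.median(np.abs(steps)) / np.sqrt(2.0) \
                if steps.size else 0.0
        else:
            sigma_hat = 0.0
        thr = min(max(0.25 * d_thresh, 2.0 * sigma_hat), 0.6 * d_thresh)
        near = np.abs(rel_raw) <= thr
        n_fr = len(mask)
        for start, stop in runs:
            while start > 0 and near[start - 1] and vis[start - 1]:
                start -= 1
            while stop < n_fr and near[stop] and vis[stop]:
                stop += 1
            grown[start:stop] = True
        for start, stop in _runs(grown):
            if stop - start < min_stance:
                continue
            seg = xy[start:stop]
            seg_vis = vis[start:stop]
            if not seg_vis.any():
                continue
            rep = tuple(np.median(seg[seg_vis], axis=0))
            events.append(StanceEvent(leg=leg, start=int(start),
                                      end=int(stop - 1), pixel=rep))
    events.sort(key=lambda e: (e.start, e.leg))
    return events


def l1_line_fit(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Least-absolute-residual line fit, y = m*x + b, returned as (m, b).

    Exact: an L1-optimal line (vertical residuals) always interpolates at
    least two of the sample points, so the fit enumerates all point pairs
    and keeps the minimum-cost candidate.  Duplicate abscissae are merged
    into their mean ordinate first (prevents duplicate-point leverage).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uu, inverse = np.unique(u, return_inverse=True)
    if uu.size < 2:
        raise ValueError("need >= 2 distinct abscissae for a line fit")
    vv = np.zeros_like(uu)
    np.add.at(vv, inverse, v)
    vv /= np.bincount(inverse)
    n = uu.size
    if n == 2:
        m = (vv[1] - vv[0]) / (uu[1] - uu[0])
        return float(m), float(vv[0] - m * uu[0])
    if n > 80:  # cap the O(n^3) enumeration; evenly thin the support
        keep = np.linspace(0, n - 1, 80).round().astype(int)
        uu, vv = uu[keep], vv[keep]
        n = uu.size
    i, j = np.triu_indices(n, k=1)
    m = (vv[j] - vv[i]) / (uu[j] - uu[i])
    b = vv[i] - m * uu[i]
    cost = np.abs(vv[None, :] - (m[:, None] * uu[None, :] + b[:, None])).sum(axis=1)
    best = int(np.argmin(cost))
    return float(m[best]), float(b[best])


def estimate_groundline(traj: TrajectorySet, stances: list[StanceEvent],
                        window: int = 15, offset_track: int = 4,
                        shift_min: float = 1.0) -> Groundline:
    """Per-frame dynamic groundline from stance-phase hoof pixels.

    For each frame, all visible stance hoof pixels within a ``window``-frame
    sliding window centred on it are fitted with a least-absolute-residual
    line.  Frames with fewer than two distinct support abscissae are marked
    invalid and filled by linear interpolation of neighbouring valid
    parameters (nearest-valid at the edges).

    A windowed fit alone cannot follow fast vertical camera motion — a
    handheld bounce both smears the offset and tilts the fitted angle,
    because support points from different instants sit on shifted copies of
    the line.  The fit is therefore translation-compensated: a per-frame
    vertical shift (median residual of the frame's own stance pixels
    against a global static line, smoothed over ``offset_track`` frames) is
    removed from the support pixels before the windowed fit and added back
    to each frame's intercept afterwards.  Set ``offset_track=0`` to
    disable the compensation.
    """
    n = traj.n_frames

    def _collect(trim: bool):
        frames_list, us, vs = [], [], []
        for ev in stances:
            xy, vis = traj.point(HOOF_KEYPOINTS[ev.leg])
            fr = ev.frames()
            if trim and len(fr) >= 5:  # edge frames may sit marginally off
                fr = fr[1:-1]
            ok = vis[fr]
            frames_list.append(fr[ok])
            us.append(xy[fr[ok], 0])
            vs.append(xy[fr[ok], 1])
        if not frames_list:
            return np.empty(0, dtype=int), np.empty(0), np.empty(0)
        fr = np.concatenate(frames_list)
        u = np.concatenate(us)
        v = np.concatenate(vs)
        order = np.argsort(fr, kind="stable")
        return fr[order], u[order], v[order]

    frames, u_all, v_all = _collect(trim=True)
    frames_s, u_s, v_s = _collect(trim=False)

    shift = np.zeros(n)
    if offset_track and frames.size >= 2:
        # Global static reference line; the per-frame median residual of
        # stance pixels against it tracks the camera's vertical motion.
        # The line itself must be fitted on motion-compensated points —
        # through the raw bouncing cloud it acquires a spurious slope that
        # turns the cycling stance x-pattern into a gait-locked offset
        # ripple — so line fit and shift estimate are iterated.
        lo_i = np.searchsorted(frames_s, np.arange(n), side="left")
        hi_i = np.searchsorted(frames_s, np.arange(n), side="right")
        idx_all = np.arange(n)
        step = max(1, frames.size // 400)
        frame_of = np.clip(frames_s, 0, n - 1)
        try:
            for _ in range(3):
                v_deb = v_s - shift[frame_of]
                m0, b0 = l1_line_fit(u_s[::step], v_deb[::step])
                resid = np.full(n, np.nan)
                for i in range(n):
                    if hi_i[i] > lo_i[i]:
                        resid[i] = np.median(v_s[lo_i[i]:hi_i[i]]
                                             - (m0 * u_s[lo_i[i]:hi_i[i]] + b0))
                ok = np.isfinite(resid)
                if ok.sum() >= 8:
                    # cubic across the short suspension gaps: the bounce
                    # has curvature there and the gaps repeat at twice the
                    # stride rate, so linear interpolation would imprint a
                    # gait-locked ripple
                    from scipy.interpolate import CubicSpline
                    cs = CubicSpline(idx_all[ok], resid[ok])
                    shift = cs(np.clip(idx_all, idx_all[ok][0], idx_all[ok][-1]))
                else:
                    shift = _interp_nan(resid)
                # zero-phase low-pass: suppresses support noise without
                # attenuating the ~1 Hz bounce as a moving average would
                cutoff = traj.fps / (2.0 * offset_track)
                if 0 < cutoff < traj.fps / 2 and n > 30:
                    sos = _signal.butter(3, cutoff, btype="lowpass",
                                         fs=traj.fps, output="sos")
                    shift = _signal.sosfiltfilt(sos, shift)
            shift -= np.median(shift)
            # a static camera needs no tracking: below ~1 px RMS the
            # "motion" is support noise, and subtracting it would only
            # inject that noise into every frame's offset
            if float(np.sqrt(np.mean(shift ** 2))) < shift_min:
                shift = np.zeros(n)
        except ValueError:
            shift = np.zeros(n)

    v_corr = v_all - shift[np.clip(frames, 0, n - 1)] if frames.size else v_all
    half = max(0, window // 2)
    angles = np.full(n, np.nan)
    offsets = np.full(n, np.nan)
    for i in range(n):
        lo = np.searchsorted(frames, i - half, side="left")
        hi = np.searchsorted(frames, i + half, side="right")
        if hi - lo < 2:
            continue
        u, v = u_all[lo:hi], v_corr[lo:hi]
        try:
            m, b = l1_line_fit(u, v)
        except ValueError:
            continue
        angles[i], offsets[i] = line_from_slope_intercept(m, b + shift[i])

    valid = np.isfinite(angles)
    if not valid.any():
        raise RuntimeError(
            f"no valid groundline frame: {len(stances)} stance events, "
            f"{frames.size} support points over {n} frames")
    idx = np.arange(n)
    angles[~valid] = np.interp(idx[~valid], idx[valid], angles[valid])
    offsets[~valid] = np.interp(idx[~valid], idx[valid], offsets[valid])
    return Groundline(angles, offsets, valid)


def rectify(traj: TrajectorySet, gl: Groundline,
            mode: str = "per_frame") -> TrajectorySet:
    """Rotate image coordinates so the groundline becomes horizontal.

    Each frame is rotated rigidly about the line's foot point (the point of
    the line nearest the image origin).  ``central_frame`` applies the
    central frame's transformation to every frame — the fixed-groundline
    control, where one marked line rectifies the whole video; ``per_frame``
    applies each frame's own line.
    """
    if mode not in ("per_frame", "central_frame"):
        raise ValueError(f"unknown rectification mode {mode!r}")
    if len(gl) != traj.n_frames:
        raise ValueError("groundline and trajectory frame counts differ")
    if mode == "central_frame":
        c = traj.n_frames // 2
        if not gl.valid[c]:
            raise ValueError(f"central frame {c} has no valid groundline")
        a = np.full(traj.n_frames, np.radians(gl.angle_deg[c]))
        off = np.full(traj.n_frames, gl.offset_px[c])
    else:
        a = np.radians(gl.angle_deg)
        off = gl.offset_px
    sin, cos = np.sin(a), np.cos(a)
    foot = np.stack([off * sin, off * cos], axis=-1)          # (n, 2)
    rot = np.stack([np.stack([cos, -sin], -1),
                    np.stack([sin, cos], -1)], axis=-2)        # (n, 2, 2)
    out = traj.copy()
    rel = out.xy - foot[:, None, :]
    out.xy = np.einsum("nij,nkj->nki", rot, rel) + foot[:, None, :]
    return out


@dataclass
class AngleErrorSummary:
    """Per-frame signed angle errors (deg) with their summary statistics."""

    errors: np.ndarray        # signed, est - ref; NaN where either invalid
    mean_signed: float
    mae: float
    n: int

    def abs_errors(self) -> np.ndarray:
        return np.abs(self.errors)


def angle_error(est: Groundline, ref: Groundline) -> AngleErrorSummary:
    """Signed per-frame angle difference est - ref, in degrees."""
    if len(est) != len(ref):
        raise ValueError(f"frame counts differ: {len(est)} vs {len(ref)}")
    errors = est.angle_deg - ref.angle_deg
    errors = np.where(est.valid & ref.valid, errors, np.nan)
    ok = np.isfinite(errors)
    if not ok.any():
        return AngleErrorSummary(errors, float("nan"), float("nan"), 0)
    return AngleErrorSummary(errors,
                             float(np.mean(errors[ok])),
                             float(np.mean(np.abs(errors[ok]))),
                             int(ok.sum()))
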