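"""Stride segmentation and Maxdiff/Mindiff symmetry metrics.

A stride runs from one stance onset of a reference forelimb to the next.
At trot the trunk rises and falls twice per stride — once per diagonal
half-cycle — so a valid stride's VDS has exactly two local maxima and two
local minima.  Maxdiff is the difference between the left- and
right-associated maxima (left minus right), Mindiff likewise for the
minima; both are ~0 in symmetric trot and grow with push-off/impact
asymmetry.  Strides containing hidden keypoint frames are excluded, never
imputed.

Extrema are measured on a per-stride two-harmonic reconstruction: the
filtered VDS inside the stride is least-squares fitted with sine/cosine
terms at the stride frequency and its double, the known (two-pass
Butterworth) filter gains at those two frequencies are divided out, and
the extrema of the compensated closed form are located on a dense grid.
This restores the stride-fundamental component that the mandatory
high-pass — cut off only 5% below the stride frequency — attenuates, and
is considerably less noise-sensitive than locating extrema sample by
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import TrajectorySet
from .groundline import StanceEvent
from .vds import VDSeries, series_gain

__all__ = ["StrideRecord", "Trial", "segment_strides", "compute_symmetry",
           "split_trials", "strides_to_dataframe"]

_RECON_GRID = 2000


@dataclass
class StrideRecord:
    """One segmented stride of a single keypoint's VDS.

    Frames are half-open [start, end).  ``left_*``/``right_*`` are the
    extrema (mm) associated with the left and right diagonal half-cycles;
    ``maxdiff``/``mindiff`` are left minus right.  Invalid strides carry a
    ``reason`` and NaN metrics.
    """

    start: int
    end: int
    reference_leg: str
    keypoint: str
    left_max: float = float("nan")
    left_min: float = float("nan")
    right_max: float = float("nan")
    right_min: float = float("nan")
    maxdiff: float = float("nan")
    mindiff: float = float("nan")
    valid: bool = False
    reason: str = ""
    mid: int | None = None    # frame splitting the two diagonal half-cycles

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("stride with end <= start")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class Trial:
    """A contiguous segment of strides, with mean symmetry metrics."""

    strides: list[StrideRecord]
    maxdiff: float
    mindiff: float
    camera_id: str = ""
    index: int = 0

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def _count_extrema(values: np.ndarray, prominence: float) -> tuple[int, int]:
    maxima, _ = find_peaks(values, prominence=prominence)
    minima, _ = find_peaks(-values, prominence=prominence)
    return len(maxima), len(minima)


def _fit_extrema(vds: VDSeries, start: int, end: int, mid: int):
    """Two-harmonic reconstruction of one stride and its per-half extrema.

    Returns ((first_max, first_min), (second_max, second_min)) where
    "first" is the half-cycle [start, mid).
    """
    y = vds.values[start:end]
    n = len(y)
    if n < 8:
        raise ValueError("stride too short for harmonic fit")
    if not np.isfinite(y).all():
        raise ValueError("stride contains hidden frames")
    # the basis is periodic at the robust global stride-frequency estimate,
    # not at 1/(boundary spacing): a one-frame onset-detection jitter would
    # otherwise leak the large symmetric 2f component into the small 1f one
    f_stride = (vds.stride_frequency_est
                if vds.stride_frequency_est else vds.fps / n)
    t = np.arange(n, dtype=float) / vds.fps      # seconds from stride start
    w1 = 2 * np.pi * f_stride
    design = np.column_stack([
        np.ones(n),
        np.sin(w1 * t), np.cos(w1 * t),
        np.sin(2 * w1 * t), np.cos(2 * w1 * t),
    ])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    rms = float(np.sqrt(np.mean((fitted - fitted.mean()) ** 2)))
    resid_frac = float(np.sqrt(np.mean((y - fitted) ** 2)) / rms) if rms > 0 else 0.0
    coef[1:3] /= series_gain(vds, f_stride)
    coef[3:5] /= series_gain(vds, 2.0 * f_stride)

    td = np.arange(_RECON_GRID) * (n / vds.fps) / _RECON_GRID
    z = (coef[0]
         + coef[1] * np.sin(w1 * td) + coef[2] * np.cos(w1 * td)
         + coef[3] * np.sin(2 * w1 * td) + coef[4] * np.cos(2 * w1 * td))
    im = int(round((mid - start) / n * _RECON_GRID))
    im = min(max(im, 1), _RECON_GRID - 1)
    first, second = z[:im], z[im:]
    return (((float(first.max()), float(first.min())),
             (float(second.max()), float(second.min()))),
            resid_frac)


def compute_symmetry(stride: StrideRecord, vds: VDSeries,
                     swap_labels: bool = False) -> tuple[float, float]:
    """(maxdiff, mindiff) in the VDS's units for one valid stride.

    ``swap_labels`` exchanges the left/right association, which negates
    both metrics exactly (the tested sign contract).  Refuses strides
    flagged invalid.
    """
    if not stride.valid:
        raise ValueError(f"stride [{stride.start}, {stride.end}) is invalid "
                         f"({stride.reason or 'unspecified'})")
    mid = stride.mid if stride.mid is not None else (stride.start + stride.end) // 2
    (first, second), _ = _fit_extrema(vds, stride.start, stride.end, mid)
    left_first = stride.reference_leg.startswith("l") ^ swap_labels
    (lmax, lmin), (rmax, rmin) = (first, second) if left_first else (second, first)
    return lmax - rmax, lmin - rmin


def segment_strides(traj: TrajectorySet, stances: list[StanceEvent],
                    vds: VDSeries, reference_leg: str | None = None,
                    min_prominence_frac: float = 0.2,
                    max_residual_frac: float = 0.2,
                    warmup_s: float = 0.0) -> list[StrideRecord]:
    """Split a filtered VDS into reference-forelimb strides and measure them.

    Stride boundaries are successive stance onsets of the reference
    forelimb (default: the left fore when detected, else the right fore);
    the contralateral fore's onset splits each stride into its two diagonal
    half-cycles, giving every extremum a left/right association.  A stride
    is excluded (not force-fitted) when the target keypoint is hidden in
    any of its frames, when its VDS does not show exactly two prominent
    maxima and two minima, when the two-harmonic stride model leaves more
    than ``max_residual_frac`` of the signal RMS unexplained (catching
    filter edge transients and other non-gait artefacts), or when it
    touches an optional warm-up margin at either end of the recording.
    A stance run truncated by the start of the recording cannot supply an
    onset and is ignored.
    """
    fore = {"lf": [], "rf": []}
    for ev in stances:
        if ev.leg in fore and ev.start > 0:
            fore[ev.leg].append(ev.start)
    if reference_leg is None:
        reference_leg = "lf" if len(fore["lf"]) >= 2 else "rf"
    if reference_leg not in ("lf", "rf"):
        raise ValueError("reference_leg must be a forelimb ('lf' or 'rf')")
    onsets = sorted(fore[reference_leg])
    if len(onsets) < 2:
        return []
    contra = sorted(fore["rf" if reference_leg == "lf" else "lf"])

    _, vis = traj.point(vds.keypoint)
    lo_ok = warmup_s * vds.fps
    hi_ok = traj.n_frames - warmup_s * vds.fps

    records: list[StrideRecord] = []
    for s, e in zip(onsets[:-1], onsets[1:]):
        mids = [o for o in contra if s < o < e]
        mid = mids[0] if len(mids) == 1 else (s + e) // 2
        rec = StrideRecord(start=s, end=e, reference_leg=reference_leg,
                           keypoint=vds.keypoint, mid=mid)
        seg = vds.values[s:e]
        if s < lo_ok or e > hi_ok:
            rec.reason = "warmup"
        elif not (vis[s:e].all() and np.isfinite(seg).all()):
            rec.reason = "occlusion"
        else:
            # count on a 2-frame-extended window so a 1-frame onset jitter
            # cannot hide a boundary extremum from the peak finder
            lo = max(s - 2, 0)
            ext = vds.values[lo:min(e + 2, len(vds.values))]
            if np.isfinite(ext).all():
                prom = min_prominence_frac * float(np.ptp(seg))
                pos_max, _ = find_peaks(ext, prominence=prom)
                pos_min, _ = find_peaks(-ext, prominence=prom)
                n_max = int(np.sum((pos_max + lo >= s - 1) & (pos_max + lo < e + 1)))
                n_min = int(np.sum((pos_min + lo >= s - 1) & (pos_min + lo < e + 1)))
            else:
                prom = min_prominence_frac * float(np.ptp(seg))
                n_max, n_min = _count_extrema(seg, prom)
            if n_max != 2 or n_min != 2:
                rec.reason = f"extrema_count ({n_max} maxima, {n_min} minima)"
        if not rec.reason:
            (first, second), resid_frac = _fit_extrema(vds, s, e, mid)
            if resid_frac > max_residual_frac:
                rec.reason = f"poor_fit (residual {resid_frac:.2f} of signal RMS)"
            else:
                rec.valid = True
                left_first = reference_leg == "lf"
                (rec.left_max, rec.left_min), (rec.right_max, rec.right_min) = \
                    (first, second) if left_first else (second, first)
                rec.maxdiff = rec.left_max - rec.right_max
                rec.mindiff = rec.left_min - rec.right_min
        records.append(rec)
    return records


def split_trials(strides: list[StrideRecord], target_len: int = 17,
                 camera_id: str = "") -> list[Trial]:
    """Partition the chronological valid strides into ~``target_len`` chunks.

    Full chunks of ``target_len`` strides; a final remainder is kept when it
    reaches at least half the target length.  Trial metrics are arithmetic
    means of the member strides'.
    """
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    valid = [s for s in strides if s.valid]
    trials: list[Trial] = []
    for k, i in enumerate(range(0, len(valid), target_len)):
        chunk = valid[i:i + target_len]
        if len(chunk) < target_len and len(chunk) < target_len / 2:
            break
        trials.append(Trial(
            strides=chunk,
            maxdiff=float(np.mean([s.maxdiff for s in chunk])),
            mindiff=float(np.mean([s.mindiff for s in chunk])),
            camera_id=camera_id, index=k))
    return trials


def strides_to_dataframe(strides: list[StrideRecord],
                         camera_id: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "stride_idx": i,
        "start_frame": s.start,
        "end_frame": s.end,
        "keypoint": s.keypoint,
        "maxdiff_mm": s.maxdiff,
        "mindiff_mm": s.mindiff,
        "valid": int(s.valid),
        "reason": s.reason,
        "camera_id": camera_id,
    } for i, s in enumerate(strides)])
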