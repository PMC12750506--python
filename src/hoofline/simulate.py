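"""Synthetic trotting-horse keypoint generator.

Generates ground-truth 3D keypoint kinematics of a horse trotting in place
on a treadmill, projects them through configurable pinhole cameras (static
or handheld), and corrupts them with detection noise and occlusion, so the
whole analysis pipeline is testable without external data.

Trunk model
-----------
At trot the trunk moves vertically twice per stride (once per diagonal
stance).  Each trunk landmark follows the two-harmonic closed form

    z(t) = z0 - A * cos(4*pi*f*t + phi_k) + a * sin(2*pi*f*t + asym_phase)

where ``f`` is the stride frequency, ``A`` (``trunk_amp``) the symmetric
second-harmonic amplitude and ``a`` (``asym_amp``) a stride-frequency
component that makes the two per-stride maxima/minima unequal — the
quantity the Maxdiff/Mindiff metrics measure.  With ``a = 0`` the gait is
perfectly symmetric.

Limb model
----------
Diagonal pairs (lf+rh, rf+lh) move in anti-phase.  During stance the hoof
is on the ground plane (z = 0) and translates backwards with the belt;
during swing it returns forward at constant horizontal velocity while
lifting along a half-sine arc of apex ``hoof_lift``.  Stance occupies
``duty_factor`` of the stride.  The reference fore hooves touch down at
stride phase 0.875 so that all four trunk extrema fall strictly inside an
onset-to-onset stride.

All keypoints lie in the sagittal plane (world y = 0): downstream analysis
is strictly 2D, and a planar horse makes stance hooves exactly collinear
with the projected ground trace in every view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .core import KEYPOINTS, LEGS, TRUNK_KEYPOINTS, Groundline, TrajectorySet, line_from_two_points

__all__ = [
    "GaitParams", "CameraModel", "WorldTrack",
    "simulate_gait", "project", "corrupt", "true_groundline",
    "symmetry_oracle", "stride_onsets", "trunk_height",
    "REFERENCE_STRIDE_PHASE", "LEG_PHASE",
]

#: stride phase (fraction) at which each leg's stance begins; diagonal
#: pairs share a phase and the two diagonals are half a stride apart.
REFERENCE_STRIDE_PHASE: float = 0.875
LEG_PHASE: dict[str, float] = {
    "lf": REFERENCE_STRIDE_PHASE, "rh": REFERENCE_STRIDE_PHASE,
    "rf": REFERENCE_STRIDE_PHASE - 0.5, "lh": REFERENCE_STRIDE_PHASE - 0.5,
}

# nominal sagittal layout (x forward, z up, mm) for a 160 cm withers horse;
# scaled linearly with withers height.  The withers landmark sits exactly at
# withers height, which is what the metric calibration relies on.
_BASE_WITHERS = 1600.0
_TRUNK_LAYOUT = {          # keypoint: (x0, z0)
    "eye": (1300.0, 1680.0),
    "withers": (300.0, 1600.0),
    "back": (-150.0, 1550.0),
    "croup": (-600.0, 1585.0),
}
_LEG_X0 = {"lf": 400.0, "rf": 400.0, "lh": -700.0, "rh": -700.0}
_JOINT_Z = {"fetlock": 120.0, "carpus": 450.0, "tarsus": 550.0}


def _as_trunk_map(value, name: str) -> dict[str, float]:
    """Scalar or per-trunk-keypoint mapping -> full mapping (incl. back)."""
    kps = TRUNK_KEYPOINTS + ("back",)
    if isinstance(value, dict):
        out = {kp: float(value.get(kp, 0.0)) for kp in kps}
    else:
        out = {kp: float(value) for kp in kps}
    for kp, v in out.items():
        if not math.isfinite(v):
            raise ValueError(f"{name}[{kp}] must be finite")
    return out


@dataclass
class GaitParams:
    """Ground-truth kinematic description of one simulated horse.

    Amplitudes are in mm, frequencies in Hz, ``withers_height`` in cm,
    ``noise_sigma`` in px.  ``trunk_amp``, ``asym_amp`` and ``trunk_phase``
    may be scalars or per-trunk-keypoint mappings.
    """

    stride_frequency: float = 1.25
    belt_speed: float = 4.8           # m/s
    duty_factor: float = 0.45
    trunk_amp: float | dict = 30.0
    asym_amp: float | dict = 0.0
    asym_phase: float = 0.0           # radians
    trunk_phase: float | dict = 0.0   # per-keypoint phi_k, radians
    hoof_lift: float = 80.0
    withers_height: float = 160.0
    duration: float = 30.0            # s
    fps: float = 30.0
    noise_sigma: float = 0.0          # px
    occlusion_rate: float = 0.0       # probability per keypoint-frame
    seed: int = 0

    def validate(self) -> None:
        def _pos(name):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0 (got {v})")

        def _nonneg(name):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")

        _pos("stride_frequency"); _pos("fps"); _pos("withers_height")
        _pos("duration"); _pos("belt_speed")
        _nonneg("hoof_lift"); _nonneg("noise_sigma")
        if not (0.0 < self.duty_factor < 1.0):
            raise ValueError(f"duty_factor must be in (0, 1) (got {self.duty_factor})")
        if not (0.0 <= self.occlusion_rate < 1.0):
            raise ValueError(f"occlusion_rate must be in [0, 1) (got {self.occlusion_rate})")
        for name in ("trunk_amp", "asym_amp"):
            amp = _as_trunk_map(getattr(self, name), name)
            if any(v < 0 for v in amp.values()):
                raise ValueError(f"{name} must be non-negative")
        _as_trunk_map(self.trunk_phase, "trunk_phase")
        if not math.isfinite(self.asym_phase):
            raise ValueError("asym_phase must be finite")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def scale(self) -> float:
        return self.withers_height * 10.0 / _BASE_WITHERS

    def with_(self, **kw) -> "GaitParams":
        return replace(self, **kw)


@dataclass
class CameraModel:
    """Pinhole camera looking at the treadmill, geometry in tabletop terms.

    ``view_angle`` is the angle between the treadmill midline and the
    horizontal viewing direction: 90 is a perpendicular side view, smaller
    angles are oblique, with ``oblique`` saying whether the camera sits
    toward the front or the rear of the horse.  ``side`` places the camera
    to the horse's right or left.  A handheld camera's origin is displaced
    each frame by a smooth seeded bounce (vertical plus half-amplitude
    horizontal) of amplitude ``bounce_amp`` at ``bounce_frequency``,
    emulating an operator stepping on the spot; its orientation stays fixed
    so the perturbation is a pure translation.
    """

    camera_id: str = "cam"
    distance_from_midline: float = 300.0   # cm
    view_angle: float = 90.0               # degrees
    height: float = 100.0                  # cm
    side: str = "right"
    oblique: str | None = None             # "front" | "rear" | None
    focal_length: float = 1500.0           # px
    image_size: tuple[int, int] = (1920, 1080)
    handheld: bool = False
    bounce_amp: float = 20.0               # mm
    bounce_frequency: float = 1.0          # Hz
    bounce_seed: int = 0
    target_height: float = 1000.0          # mm, look-at height on the midline

    def validate(self) -> None:
        if not (0.0 < self.view_angle <= 90.0):
            raise ValueError(f"view_angle must be in (0, 90] (got {self.view_angle})")
        if self.distance_from_midline <= 0:
            raise ValueError("distance_from_midline must be > 0")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left' (got {self.side!r})")
        if self.oblique not in (None, "front", "rear"):
            raise ValueError(f"oblique must be None, 'front' or 'rear' (got {self.oblique!r})")
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")
        if self.bounce_amp < 0 or self.bounce_frequency <= 0:
            raise ValueError("bounce_amp must be >= 0 and bounce_frequency > 0")

    # ---- pose ----

    def position(self) -> np.ndarray:
        """Nominal camera origin in world coordinates (mm)."""
        d = self.distance_from_midline * 10.0
        y = -d if self.side == "right" else d
        x = 0.0
        if self.oblique is not None and self.view_angle < 90.0:
            dx = d / math.tan(math.radians(self.view_angle))
            x = dx if self.oblique == "front" else -dx
        return np.array([x, y, self.height * 10.0])

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, down, forward) unit vectors of the camera frame."""
        target = np.array([0.0, 0.0, self.target_height])
        fwd = target - self.position()
        fwd = fwd / np.linalg.norm(fwd)
        up = np.array([0.0, 0.0, 1.0])
        right = np.cross(fwd, up)
        nr = np.linalg.norm(right)
        if nr < 1e-9:
            raise ValueError("degenerate camera pose: looking straight down")
        right /= nr
        down = np.cross(fwd, right)
        return right, down, fwd

    def principal_point(self) -> tuple[float, float]:
        return self.image_size[0] / 2.0, self.image_size[1] / 2.0

    def bounce_offsets(self, n_frames: int, fps: float) -> np.ndarray:
        """Per-frame world-space displacement of the camera origin (mm).

        Zero for a static camera.  For handheld: a seeded sinusoid at
        ``bounce_frequency`` plus low-pass-filtered jitter, vertically, and
        a half-amplitude independent copy along the camera's horizontal
        right axis.
        """
        if not self.handheld or self.bounce_amp == 0.0:
            return np.zeros((n_frames, 3))
        rng = np.random.default_rng(self.bounce_seed)
        t = np.arange(n_frames) / fps
        ph_v, ph_h = rng.uniform(0.0, 2.0 * np.pi, size=2)
        vert = self.bounce_amp * np.sin(2 * np.pi * self.bounce_frequency * t + ph_v)
        horiz = 0.5 * self.bounce_amp * np.sin(2 * np.pi * self.bounce_frequency * t + ph_h)
        if n_frames > 30:  # add smooth jitter when the run is long enough to filter
            sos = _signal.butter(2, 2.0, btype="lowpass", fs=fps, output="sos")
            for target, scale in ((vert, 0.25), (horiz, 0.125)):
                jit = _signal.sosfiltfilt(sos, rng.standard_normal(n_frames))
                sd = jit.std()
                if sd > 0:
                    target += scale * self.bounce_amp * jit / sd
        right, _, _ = self.basis()
        horiz_dir = np.array([right[0], right[1], 0.0])
        nh = np.linalg.norm(horiz_dir)
        horiz_dir = horiz_dir / nh if nh > 0 else np.zeros(3)
        return vert[:, None] * np.array([0.0, 0.0, 1.0]) + horiz[:, None] * horiz_dir


@dataclass
class WorldTrack:
    """Ground-truth per-frame 3D keypoint positions and stance flags."""

    xyz: np.ndarray               # (n_frames, n_keypoints, 3) mm
    stance: np.ndarray            # (n_frames, 4) bool, column order = LEGS
    fps: float
    keypoints: tuple[str, ...] = KEYPOINTS
    legs: tuple[str, ...] = LEGS

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def point(self, keypoint: str) -> np.ndarray:
        return self.xyz[:, self.keypoints.index(keypoint), :]

    def leg_stance(self, leg: str) -> np.ndarray:
        return self.stance[:, self.legs.index(leg)]


def trunk_height(params: GaitParams, keypoint: str, t: np.ndarray) -> np.ndarray:
    """Closed-form vertical trajectory z(t) (mm) of a trunk keypoint."""
    params.validate()
    if keypoint not in TRUNK_KEYPOINTS + ("back",):
        raise KeyError(f"{keypoint!r} is not a trunk keypoint")
    t = np.asarray(t, dtype=float)
    f = params.stride_frequency
    amp = _as_trunk_map(params.trunk_amp, "trunk_amp")[keypoint]
    asym = _as_trunk_map(params.asym_amp, "asym_amp")[keypoint]
    phase = _as_trunk_map(params.trunk_phase, "trunk_phase")[keypoint]
    z0 = _TRUNK_LAYOUT[keypoint][1] * params.scale
    return (z0
            - amp * np.cos(4 * np.pi * f * t + phase)
            + asym * np.sin(2 * np.pi * f * t + params.asym_phase))


def _hoof_kinematics(params: GaitParams, leg: str, t: np.ndarray):
    """(x, z, stance) of one hoof over time."""
    f = params.stride_frequency
    duty = params.duty_factor
    x0 = _LEG_X0[leg] * params.scale
    travel = params.belt_speed * 1000.0 * duty / f
    phase = np.mod(f * t - LEG_PHASE[leg], 1.0)
    stance = phase < duty
    x = np.empty_like(phase)
    z = np.zeros_like(phase)
    s = phase / duty                       # stance progress
    w = (phase - duty) / (1.0 - duty)      # swing progress
    x = np.where(stance, x0 + travel * (0.5 - s), x0 + travel * (w - 0.5))
    z = np.where(stance, 0.0, params.hoof_lift * np.sin(np.pi * np.clip(w, 0.0, 1.0)))
    return x, z, stance


def simulate_gait(params: GaitParams) -> WorldTrack:
    """Generate the ground-truth world-frame track for one horse.

    Deterministic given ``params``: no randomness is involved at this stage
    (noise and occlusion are applied later, in image space, by
    :func:`corrupt`).
    """
    params.validate()
    t = np.arange(params.n_frames) / params.fps
    n = t.size
    xyz = np.zeros((n, len(KEYPOINTS), 3))
    kp_index = {kp: i for i, kp in enumerate(KEYPOINTS)}

    for kp in TRUNK_KEYPOINTS + ("back",):
        i = kp_index[kp]
        xyz[:, i, 0] = _TRUNK_LAYOUT[kp][0] * params.scale
        xyz[:, i, 2] = trunk_height(params, kp, t)

    stance = np.zeros((n, len(LEGS)), dtype=bool)
    for j, leg in enumerate(LEGS):
        hx, hz, st = _hoof_kinematics(params, leg, t)
        stance[:, j] = st
        x0 = _LEG_X0[leg] * params.scale
        i = kp_index[f"{leg}_hoof"]
        xyz[:, i, 0] = hx
        xyz[:, i, 2] = hz
        i = kp_index[f"{leg}_fetlock"]
        xyz[:, i, 0] = hx + 40.0 * params.scale
        xyz[:, i, 2] = _JOINT_Z["fetlock"] * params.scale + 0.5 * hz
        joint = "carpus" if leg in ("lf", "rf") else "tarsus"
        i = kp_index[f"{leg}_{joint}"]
        xyz[:, i, 0] = x0 + 0.35 * (hx - x0)
        xyz[:, i, 2] = _JOINT_Z[joint] * params.scale + 0.25 * hz

    return WorldTrack(xyz=xyz, stance=stance, fps=params.fps)


def _project_points(points: np.ndarray, origins: np.ndarray, cam: CameraModel):
    """Project (n, k, 3) world points through per-frame origins (n, 3)."""
    right, down, fwd = cam.basis()
    q = points - origins[:, None, :]
    xc = q @ right
    yc = q @ down
    zc = q @ fwd
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.focal_length * xc / zc
        v = cam.focal_length * yc / zc
    cx, cy = cam.principal_point()
    u = u + cx
    v = v + cy
    in_front = zc > 1.0
    return u, v, in_front


def project(world: WorldTrack, cam: CameraModel) -> TrajectorySet:
    """Pinhole projection of a world track into one camera's image plane.

    Keypoints behind the camera plane or outside the image bounds are
    marked not visible (their coordinates are still reported, letting
    callers inspect where they would have fallen).
    """
    cam.validate()
    n = world.n_frames
    origins = cam.position()[None, :] + cam.bounce_offsets(n, world.fps)
    u, v, in_front = _project_points(world.xyz, origins, cam)
    w, h = cam.image_size
    visible = in_front & (u >= 0) & (u < w) & (v >= 0) & (v < h)
    xy = np.stack([u, v], axis=-1)
    xy[~in_front] = np.nan
    return TrajectorySet(xy=xy, visible=visible, fps=world.fps,
                         keypoints=world.keypoints, camera_id=cam.camera_id)


def corrupt(traj: TrajectorySet, noise_sigma: float, occlusion_rate: float,
            seed: int) -> TrajectorySet:
    """Add detection noise and occlusion to a trajectory set.

    Adds i.i.d. Gaussian pixel noise to visible keypoints and independently
    flips visibility to False with probability ``occlusion_rate`` per
    keypoint-frame.  Reproducible under ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not (0.0 <= occlusion_rate < 1.0):
        raise ValueError("occlusion_rate must be in [0, 1)")
    out = traj.copy()
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=out.xy.shape)
        out.xy[out.visible] += noise[out.visible]
    if occlusion_rate > 0:
        keep = rng.random(out.visible.shape) >= occlusion_rate
        out.visible &= keep
    return out


def true_groundline(world: WorldTrack, cam: CameraModel) -> Groundline:
    """Project the treadmill midline ground trace into image coordinates.

    For a static camera this is the constant "fixed groundline" control
    (what an operator marks from the physical treadmill base); for a
    handheld camera the line moves with the bounce.
    """
    cam.validate()
    n = world.n_frames
    ends = np.array([[-4000.0, 0.0, 0.0], [4000.0, 0.0, 0.0]])
    if cam.handheld:
        origins = cam.position()[None, :] + cam.bounce_offsets(n, world.fps)
        u, v, in_front = _project_points(np.broadcast_to(ends, (n, 2, 3)), origins, cam)
        angles = np.empty(n)
        offsets = np.empty(n)
        for i in range(n):
            angles[i], offsets[i] = line_from_two_points((u[i, 0], v[i, 0]),
                                                         (u[i, 1], v[i, 1]))
        return Groundline(angles, offsets)
    u, v, _ = _project_points(ends[None, :, :], cam.position()[None, :], cam)
    angle, offset = line_from_two_points((u[0, 0], v[0, 0]), (u[0, 1], v[0, 1]))
    return Groundline.fixed(angle, offset, n)


def stride_onsets(params: GaitParams, leg: str = "lf") -> np.ndarray:
    """Ground-truth stance-onset times (s) of one leg within the recording."""
    f = params.stride_frequency
    first = LEG_PHASE[leg] / f
    k = np.arange(int(np.floor((params.duration - first) * f)) + 1)
    return first + k / f


def symmetry_oracle(params: GaitParams, keypoint: str = "withers",
                    n_grid: int = 10_000):
    """Ground-truth per-stride Maxdiff/Mindiff by dense-grid extrema search.

    Evaluates the closed-form trunk trajectory on ``n_grid`` samples per
    stride, splits each reference-fore stride into its two diagonal
    half-cycles, and differences the per-half extrema (left half minus
    right half).  This is the reference every downstream recovery test is
    compared against.

    Returns (onset_times, maxdiff, mindiff) for every complete stride.
    """
    params.validate()
    f = params.stride_frequency
    onsets = stride_onsets(params)
    onsets = onsets[onsets + 1.0 / f <= params.duration + 1e-9]
    if len(onsets) == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    maxdiff = np.empty(len(onsets))
    mindiff = np.empty(len(onsets))
    half = n_grid // 2
    for i, t0 in enumerate(onsets):
        tt = t0 + np.arange(n_grid) / (n_grid * f)
        z = trunk_height(params, keypoint, tt)
        left, right_ = z[:half], z[half:]
        maxdiff[i] = left.max() - right_.max()
        mindiff[i] = left.min() - right_.min()
    return onsets, maxdiff, mindiff
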