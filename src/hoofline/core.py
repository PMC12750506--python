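"""Shared containers and image-plane geometry.

Conventions used throughout the package (stated once, here):

* image coordinates: origin top-left, x to the right, y downward, units px,
  0-based frame indexing;
* world coordinates: treadmill-fixed right-handed frame, x in the direction
  the horse faces, y to the horse's left, z up, units mm, ground plane z = 0;
* groundline angle: degrees in (-90, 90], positive when the line rises
  left-to-right on screen (i.e. image y decreases as x increases);
* groundline offset: signed perpendicular distance of the line from the
  image origin, px; a horizontal line at image row y0 has offset y0.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: the 16 landmarks placed on every frame: four trunk points and, per leg,
#: hoof / fetlock / carpus (fore) or tarsus (hind).  Legs are named by side
#: and girdle: lf/rf fore, lh/rh hind.
KEYPOINTS: tuple[str, ...] = (
    "eye",
    "withers",
    "back",
    "croup",
    "lf_hoof", "lf_fetlock", "lf_carpus",
    "rf_hoof", "rf_fetlock", "rf_carpus",
    "lh_hoof", "lh_fetlock", "lh_tarsus",
    "rh_hoof", "rh_fetlock", "rh_tarsus",
)

#: trunk landmarks whose vertical displacement signal is analysed
TRUNK_KEYPOINTS: tuple[str, ...] = ("eye", "withers", "croup")

LEGS: tuple[str, ...] = ("lf", "rf", "lh", "rh")

HOOF_KEYPOINTS: dict[str, str] = {leg: f"{leg}_hoof" for leg in LEGS}


def _norm_angle(angle_deg: np.ndarray | float):
    """Map an angle in degrees to the equivalent line angle in (-90, 90]."""
    a = (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0
    # boundary: prefer +90 over -90
    a = np.where(np.isclose(a, -90.0), 90.0, a)
    return a if a.ndim else float(a)


def line_from_two_points(p1, p2) -> tuple[float, float]:
    """Line parameters (angle_deg, offset_px) through two image points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    du, dv = p2 - p1
    if du == 0.0 and dv == 0.0:
        raise ValueError("coincident points do not define a line")
    angle = _norm_angle(np.degrees(np.arctan2(-dv, du)))
    a = np.radians(angle)
    offset = p1[0] * np.sin(a) + p1[1] * np.cos(a)
    return float(angle), float(offset)


def line_from_slope_intercept(m: float, b: float) -> tuple[float, float]:
    """Convert y = m*x + b (image coords) to (angle_deg, offset_px)."""
    angle = float(np.degrees(np.arctan2(-m, 1.0)))
    offset = b * float(np.cos(np.radians(angle)))
    return angle, offset


def height_above_line(angle_deg, offset_px, xy) -> np.ndarray:
    """Signed perpendicular distance of image points above a line (px).

    Positive for points on the visually *upper* side (smaller y for a
    horizontal line).  ``xy`` has shape (..., 2); angle/offset broadcast
    against its leading dimensions.
    """
    xy = np.asarray(xy, dtype=float)
    a = np.radians(np.asarray(angle_deg, dtype=float))
    return np.asarray(offset_px) - (xy[..., 0] * np.sin(a) + xy[..., 1] * np.cos(a))


@dataclass
class TrajectorySet:
    """Per-frame 2D pixel keypoints with visibility flags.

    The interchange currency of the pipeline: the simulator produces one per
    camera, and every analysis stage consumes one.
    """

    xy: np.ndarray            # (n_frames, n_keypoints, 2) float px
    visible: np.ndarray       # (n_frames, n_keypoints) bool
    fps: float
    keypoints: tuple[str, ...] = KEYPOINTS
    sync_offset: int = 0      # frames relative to the session's shared clock
    camera_id: str = ""

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.xy.shape[:2] != self.visible.shape:
            raise ValueError("xy and visible shapes disagree")
        if self.xy.shape[1] != len(self.keypoints):
            raise ValueError("keypoint axis does not match keypoint names")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def index(self, keypoint: str) -> int:
        try:
            return self.keypoints.index(keypoint)
        except ValueError:
            raise KeyError(f"unknown keypoint {keypoint!r}") from None

    def point(self, keypoint: str) -> tuple[np.ndarray, np.ndarray]:
        """(xy, visible) for one keypoint; xy has shape (n_frames, 2)."""
        k = self.index(keypoint)
        return self.xy[:, k, :], self.visible[:, k]

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(self.xy.copy(), self.visible.copy(), self.fps,
                             self.keypoints, self.sync_offset, self.camera_id)

    # ---- serialization (long CSV, one row per keypoint-frame) ----

    def to_dataframe(self) -> pd.DataFrame:
        n, k = self.visible.shape
        frames = np.repeat(np.arange(n), k)
        return pd.DataFrame({
            "frame": frames,
            "time_s": frames / self.fps,
            "keypoint": np.tile(np.asarray(self.keypoints, dtype=object), n),
            "x_px": self.xy[..., 0].ravel(),
            "y_px": self.xy[..., 1].ravel(),
            "visible": self.visible.ravel().astype(int),
        })

    def to_csv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# hoofline trajectory v1 fps={self.fps} "
                     f"camera={self.camera_id} sync_offset={self.sync_offset}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        path = Path(path)
        text = path.read_text()
        header, _, body = text.partition("\n")
        if not header.startswith("# hoofline trajectory"):
            raise ValueError(f"{path}: not a hoofline trajectory CSV")
        meta = dict(tok.split("=", 1) for tok in header.split() if "=" in tok)
        df = pd.read_csv(_io.StringIO(body))
        kps = tuple(dict.fromkeys(df["keypoint"]))
        n = int(df["frame"].max()) + 1
        xy = np.full((n, len(kps), 2), np.nan)
        vis = np.zeros((n, len(kps)), dtype=bool)
        kp_idx = {kp: i for i, kp in enumerate(kps)}
        rows = df["frame"].to_numpy()
        cols = df["keypoint"].map(kp_idx).to_numpy()
        xy[rows, cols, 0] = df["x_px"].to_numpy()
        xy[rows, cols, 1] = df["y_px"].to_numpy()
        vis[rows, cols] = df["visible"].to_numpy().astype(bool)
        return cls(xy, vis, fps=float(meta["fps"]), keypoints=kps,
                   sync_offset=int(meta.get("sync_offset", 0)),
                   camera_id=meta.get("camera", ""))


@dataclass
class Groundline:
    """Per-frame image-plane line: angle (deg) and offset (px).

    ``dynamic`` lines vary frame to frame (estimated from hoof keypoints, or
    the true ground trace of a moving camera); a ``fixed`` line repeats the
    same parameters on every frame, mirroring a groundline marked once from
    the treadmill base.
    """

    angle_deg: np.ndarray
    offset_px: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.angle_deg = np.atleast_1d(np.asarray(self.angle_deg, dtype=float))
        self.offset_px = np.atleast_1d(np.asarray(self.offset_px, dtype=float))
        if self.valid is None:
            self.valid = np.isfinite(self.angle_deg) & np.isfinite(self.offset_px)
        self.valid = np.atleast_1d(np.asarray(self.valid, dtype=bool))
        if not (len(self.angle_deg) == len(self.offset_px) == len(self.valid)):
            raise ValueError("angle, offset and valid lengths disagree")
        finite = self.angle_deg[np.isfinite(self.angle_deg)]
        if finite.size and (finite.max() > 90.0 or finite.min() <= -90.0):
            raise ValueError("groundline angle outside (-90, 90] degrees")

    def __len__(self) -> int:
        return len(self.angle_deg)

    @classmethod
    def fixed(cls, angle_deg: float, offset_px: float, n_frames: int) -> "Groundline":
        return cls(np.full(n_frames, float(angle_deg)),
                   np.full(n_frames, float(offset_px)),
                   np.ones(n_frames, dtype=bool))

    @property
    def is_fixed(self) -> bool:
        return bool(np.all(self.angle_deg == self.angle_deg[0])
                    and np.all(self.offset_px == self.offset_px[0]))

    def at(self, frame: int) -> tuple[float, float]:
        return float(self.angle_deg[frame]), float(self.offset_px[frame])

    def height_of(self, xy: np.ndarray) -> np.ndarray:
        """Per-frame signed height (px) of points above the line.

        ``xy``: (n_frames, 2) array matched frame-by-frame to the line.
        """
        return height_above_line(self.angle_deg, self.offset_px, xy)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "frame": np.arange(len(self)),
            "angle_deg": self.angle_deg,
            "offset_px": self.offset_px,
            "valid": self.valid.astype(int),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Groundline":
        df = pd.read_csv(path)
        return cls(df["angle_deg"].to_numpy(), df["offset_px"].to_numpy(),
                   df["valid"].to_numpy().astype(bool))


def as_jsonable(obj):
    """Recursively convert dataclasses / numpy scalars for json.dump."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(as_jsonable(obj), indent=2, sort_keys=True))
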