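"""Core containers shared across the tracking and analysis modules.

Coordinate conventions
----------------------
All physical positions are in millimetres: ``x`` increases in the direction
of walking, ``y`` is lateral with the corridor midline at 0 and the animal's
right positive, ``z`` is height above the corridor floor.  Image coordinates
are 0-based ``(row, col)`` pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: canonical feature names, in canonical order
PAWS = ("FR", "FL", "HR", "HL")
TAIL_SEGMENTS = tuple(f"tail_{i}" for i in range(1, 16))
FEATURES = PAWS + ("snout",) + TAIL_SEGMENTS + ("body_center",)


@dataclass
class FrameImage:
    """A single composite corridor frame (side view above, bottom view below)."""

    pixels: np.ndarray            # 2D float array, intensities in [0, 1]
    view_split_row: int           # first row of the bottom view
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2D array")
        if not 0 < self.view_split_row < self.pixels.shape[0]:
            raise ValueError("view_split_row must lie strictly inside the image")

    @property
    def side(self) -> np.ndarray:
        return self.pixels[: self.view_split_row]

    @property
    def bottom(self) -> np.ndarray:
        return self.pixels[self.view_split_row:]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box: rows [row_min, row_max), cols [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError(f"empty bounding box: {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_min + self.row_max - 1) / 2.0,
                (self.col_min + self.col_max - 1) / 2.0)

    def contains(self, row: float, col: float) -> bool:
        return (self.row_min <= row < self.row_max
                and self.col_min <= col < self.col_max)


@dataclass
class Candidate:
    """A scored candidate location for one feature class in one view."""

    feature_class: str            # "paw" | "snout" | "tail"
    view: str                     # "bottom" | "side"
    position: tuple[float, float]  # (col, row) in image pixels
    score: float
    moving: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("candidate score must be finite")


@dataclass
class FrameCandidates:
    """Candidates available for one feature class in one frame.

    ``positions`` is (n, 2) ``(col, row)``; ``scores`` is (n_objects, n):
    the detection score of each candidate as seen by each tracked object
    (object-dependent because the location prior differs per object).
    """

    positions: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[1] != self.positions.shape[0]:
            raise ValueError("scores and positions disagree on candidate count")

    @property
    def n_candidates(self) -> int:
        return self.positions.shape[0]


@dataclass
class CandidateGraph:
    """Per-frame candidate sets plus the transition model of the MAP tracker.

    The tracker maximizes
    ``C(x) = sum_o [ sum_t U(x_{o,t}) + alpha * sum_t P(x_{o,t}, x_{o,t+1}) ]``
    where ``U`` is the prior-weighted detection score, ``P = 1/(1+d)`` the
    inverse image distance, and transitions longer than
    ``box_displacement[t] + v_base`` pixels are infeasible.
    """

    frames: list[FrameCandidates]
    alpha: float = 0.1
    v_base: float = 15.0
    box_displacement: np.ndarray | None = None   # per transition, px

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.v_base <= 0:
            raise ValueError("v_base must be > 0")
        n_trans = max(len(self.frames) - 1, 0)
        if self.box_displacement is None:
            self.box_displacement = np.zeros(n_trans)
        self.box_displacement = np.asarray(self.box_displacement, dtype=float)
        if self.box_displacement.shape != (n_trans,):
            raise ValueError("box_displacement must have one entry per frame transition")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_objects(self) -> int:
        return self.frames[0].scores.shape[0] if self.frames else 0

    def v_limit(self, t: int) -> float:
        """Maximum feasible displacement between frames t and t+1, px."""
        return float(self.box_displacement[t] + self.v_base)


class TrackSet:
    """Per-frame 3D positions (mm) of the tracked body features.

    Features map to float arrays of shape (n_frames, 3) with columns
    ``x, y, z``; NaN marks frames where a feature was not located.
    """

    def __init__(self, features: Mapping[str, np.ndarray], fps: float,
                 px_per_mm: float = 1.0, trial_id: str = "trial",
                 meta: dict | None = None):
        self.features: dict[str, np.ndarray] = {}
        n = None
        for name, arr in features.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"feature {name!r} must be (n_frames, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all features must share the frame count")
            self.features[name] = arr
        if n is None:
            raise ValueError("TrackSet needs at least one feature")
        self.n_frames = n
        self.fps = float(fps)
        self.px_per_mm = float(px_per_mm)
        self.trial_id = trial_id
        self.meta = dict(meta or {})

    def __getitem__(self, name: str) -> np.ndarray:
        return self.features[name]

    def __contains__(self, name: str) -> bool:
        return name in self.features

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def x(self, name: str) -> np.ndarray:
        return self.features[name][:, 0]

    def y(self, name: str) -> np.ndarray:
        return self.features[name][:, 1]

    def z(self, name: str) -> np.ndarray:
        return self.features[name][:, 2]

    def body_center_x(self) -> np.ndarray:
        """Forward body-center track; centroid of the paw x positions if no
        dedicated body_center feature is present."""
        if "body_center" in self.features:
            return self.x("body_center")
        paws = [self.x(p) for p in PAWS if p in self.features]
        if not paws:
            raise ValueError("no body_center and no paw tracks available")
        return np.nanmean(np.vstack(paws), axis=0)


@dataclass
class MouseMeta:
    """Subject metadata attached to stride tables."""

    subject_id: str = "subject"
    weight_g: float = 20.0
    body_length_mm: float = 80.0
    age_days: float | None = None
    gender: str | None = None
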