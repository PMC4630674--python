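"""Stride segmentation and single-limb kinematic parameters.

A stride runs from one stance onset (touchdown) to the next.  Stance and
swing are separated on the first derivative of the forward paw position:
during stance the paw is stationary on the glass, during swing it moves
forward rapidly.  Each stride yields duration, length, cadence, stance and
swing durations, swing velocity, peak vertical excursion, and the walking
speed of the body during that stride — the unit of all downstream
statistics, which are aggregated in 0.05 m/s walking-speed bins with at
least 5 strides per bin per animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from .core import PAWS, MouseMeta, TrackSet

logger = logging.getLogger(__name__)

STRIDE_COLUMNS = [
    "paw", "stance_onset", "swing_onset", "next_stance_onset",
    "stride_duration", "stance_duration", "swing_duration", "cadence",
    "stride_length", "swing_velocity", "peak_swing_velocity", "peak_z",
    "walking_speed",
]


def smoothed_velocity(x: np.ndarray, fps: float, window: int = 3) -> np.ndarray:
    """Forward velocity (mm/s) by central differences after first-order
    Savitzky-Golay smoothing with a 3-point window."""
    x = np.asarray(x, dtype=float)
    if len(x) >= window:
        x = savgol_filter(x, window_length=window, polyorder=1)
    return np.gradient(x) * fps


def detect_stance_swing(x_track: np.ndarray, fps: float,
                        velocity_threshold: float = 20.0,
                        hysteresis_frames: int = 3,
                        min_phase_frames: int = 5,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Stance and swing onsets from the forward-position derivative.

    Classification uses two thresholds on the forward velocity (central
    differences, mm/s): a frame is definitely stance below
    ``velocity_threshold`` and definitely swing above twice it; in between
    the previous state persists (a Schmitt trigger, which keeps measurement
    noise from chattering across a single threshold).  Pre-smoothing the
    position trace is deliberately avoided: a centered smoother leaks swing
    displacement across the touchdown frame and biases onsets by up to two
    frames.  On top of the trigger, a width-3 boolean median removes
    isolated misclassified frames, a phase change must persist
    ``hysteresis_frames`` frames (and is then backdated to where it
    started), and runs shorter than ``min_phase_frames`` are merged into
    their neighbors.  Returns ``(stance_onsets, swing_onsets)`` as frame
    indices; a trace without alternation yields empty lists and a warning.
    """
    x = np.asarray(x_track, dtype=float)
    if len(x) < 2 * min_phase_frames:
        logger.warning("track too short for stride segmentation")
        return np.array([], dtype=int), np.array([], dtype=int)
    vel = np.gradient(x) * fps
    speed = np.abs(vel)
    # Schmitt trigger: < theta -> stance, > 2*theta -> swing, else hold
    stance = np.empty(len(speed), dtype=bool)
    current = bool(speed[0] < 2 * velocity_threshold)
    for i, v in enumerate(speed):
        if v < velocity_threshold:
            current = True
        elif v > 2 * velocity_threshold:
            current = False
        stance[i] = current
    if len(stance) >= 3:
        # remove isolated single-frame misclassifications; a width-3 boolean
        # median keeps true transitions in place
        from scipy.ndimage import median_filter
        stance = median_filter(stance, size=3, mode="nearest")

    # hysteresis with backdating: flip state once `hysteresis_frames`
    # consistent frames accumulate, then relabel from the run start
    state = bool(stance[0])
    run_start: int | None = None
    labels = np.empty(len(stance), dtype=bool)
    for i, s in enumerate(stance):
        if s != state:
            if run_start is None:
                run_start = i
            if i - run_start + 1 >= hysteresis_frames:
                state = s
                labels[run_start:i + 1] = state
                run_start = None
            else:
                labels[i] = state
        else:
            run_start = None
            labels[i] = state

    # merge runs shorter than the minimum phase duration
    changed = True
    while changed:
        changed = False
        edges = np.flatnonzero(np.diff(labels.astype(int))) + 1
        bounds = np.concatenate([[0], edges, [len(labels)]])
        lengths = np.diff(bounds)
        if len(lengths) <= 1:
            break
        shortest = int(np.argmin(lengths))
        if lengths[shortest] < min_phase_frames:
            labels[bounds[shortest]:bounds[shortest + 1]] = \
                ~labels[bounds[shortest]]
            changed = True

    trans = np.diff(labels.astype(int))
    stance_onsets = np.flatnonzero(trans == 1) + 1
    swing_onsets = np.flatnonzero(trans == -1) + 1
    if labels[0]:
        stance_onsets = np.concatenate([[0], stance_onsets])
    if len(stance_onsets) == 0 or len(swing_onsets) == 0:
        logger.warning("no stance/swing alternation found")
        return np.array([], dtype=int), np.array([], dtype=int)
    return stance_onsets.astype(int), swing_onsets.astype(int)


def stride_length(x_track: np.ndarray, stance_onset: int,
                  next_stance_onset: int) -> float:
    """Forward displacement of the limb from touchdown to next touchdown."""
    return float(x_track[next_stance_onset] - x_track[stance_onset])


@dataclass
class StrideTable:
    """One row per stride per paw plus the subject's metadata."""

    data: pd.DataFrame
    meta: MouseMeta = field(default_factory=MouseMeta)
    fps: float = 400.0

    def __len__(self) -> int:
        return len(self.data)

    def for_paw(self, paw: str) -> pd.DataFrame:
        return self.data[self.data["paw"] == paw]


def build_strides(tracks: TrackSet, meta: MouseMeta | None = None,
                  paws: tuple[str, ...] = PAWS,
                  velocity_threshold: float = 20.0,
                  hysteresis_frames: int = 3,
                  min_phase_frames: int = 5) -> StrideTable:
    """Segment every paw track into strides and compute per-stride parameters.

    Walking speed is the forward motion of the body center over the stride
    divided by the stride duration.  Incomplete trailing cycles are dropped;
    a mid-trial halt simply yields separate strides on either side of it.
    """
    fps = tracks.fps
    body_x = tracks.body_center_x()
    rows = []
    for paw in paws:
        x = tracks.x(paw)
        z = tracks.z(paw)
        stance_on, swing_on = detect_stance_swing(
            x, fps, velocity_threshold, hysteresis_frames, min_phase_frames)
        for k in range(len(stance_on) - 1):
            s0, s1 = int(stance_on[k]), int(stance_on[k + 1])
            sw = swing_on[(swing_on > s0) & (swing_on < s1)]
            if len(sw) != 1:
                continue
            sw = int(sw[0])
            stride_dur = (s1 - s0) / fps
            stance_dur = (sw - s0) / fps
            swing_dur = (s1 - sw) / fps
            swing_disp = x[s1] - x[sw]
            vel = smoothed_velocity(x[sw:s1 + 1], fps)
            zswing = z[sw:s1 + 1]
            rows.append({
                "paw": paw,
                "stance_onset": s0, "swing_onset": sw, "next_stance_onset": s1,
                "stride_duration": stride_dur,
                "stance_duration": stance_dur,
                "swing_duration": swing_dur,
                "cadence": 1.0 / stride_dur,
                "stride_length": stride_length(x, s0, s1),
                "swing_velocity": swing_disp / swing_dur / 1000.0,   # m/s
                "peak_swing_velocity": float(np.nanmax(vel)) / 1000.0,
                "peak_z": float(np.nanmax(zswing)) if np.isfinite(zswing).any() else np.nan,
                "walking_speed": (body_x[s1] - body_x[s0]) / stride_dur / 1000.0,
            })
    df = pd.DataFrame(rows, columns=STRIDE_COLUMNS)
    return StrideTable(data=df, meta=meta or MouseMeta(), fps=fps)


def bin_by_speed(table: StrideTable | pd.DataFrame, bin_width: float = 0.05,
                 min_strides: int = 5,
                 value_columns: list[str] | None = None) -> pd.DataFrame:
    """Stride-wise speed binning with per-animal medians.

    Strides are assigned to half-open walking-speed bins
    ``[k*bin_width, (k+1)*bin_width)`` anchored at zero; for each animal a
    bin is retained only when it holds at least ``min_strides`` strides.
    Returns a tidy frame with columns ``subject, paw, speed_bin`` (bin lower
    edge), ``n_strides`` and the median of each value column.
    """
    if isinstance(table, StrideTable):
        df = table.data.copy()
        df["subject"] = table.meta.subject_id
    else:
        df = table.copy()
        if "subject" not in df:
            df["subject"] = "subject"
    if value_columns is None:
        value_columns = [c for c in df.columns
                         if c not in ("paw", "subject")
                         and np.issubdtype(df[c].dtype, np.number)]
    df["speed_bin"] = np.floor(df["walking_speed"] / bin_width) * bin_width
    out = []
    for (subject, paw, sbin), grp in df.groupby(["subject", "paw", "speed_bin"]):
        if len(grp) < min_strides:
            continue
        row = {"subject": subject, "paw": paw,
               "speed_bin": round(float(sbin), 10), "n_strides": len(grp)}
        for c in value_columns:
            row[c] = float(grp[c].median())
        out.append(row)
    return pd.DataFrame(out)


def normalize_trajectory(segment: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a per-stride trajectory segment to ``n_points`` equidistant
    samples by linear interpolation (endpoints preserved)."""
    seg = np.asarray(segment, dtype=float)
    if seg.shape[0] < 2:
        raise ValueError("trajectory segment needs at least 2 samples")
    t_old = np.linspace(0.0, 1.0, seg.shape[0])
    t_new = np.linspace(0.0, 1.0, n_points)
    if seg.ndim == 1:
        return interp1d(t_old, seg)(t_new)
    return interp1d(t_old, seg, axis=0)(t_new)


def average_trajectory(segments: list[np.ndarray], n_points: int = 100,
                       smooth: bool = True) -> np.ndarray:
    """Phase-align stride segments to a common 100-point axis, average, and
    smooth with a first-order Savitzky-Golay filter (3-point window)."""
    resampled = np.stack([normalize_trajectory(s, n_points) for s in segments])
    mean = np.nanmean(resampled, axis=0)
    if smooth and n_points >= 3:
        mean = savgol_filter(mean, window_length=3, polyorder=1, axis=0)
    return mean
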