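"""Passive geometric model of tail and nose oscillation.

The model asks what lateral tail and nose motion would result *purely
passively* from the alternating forward motion of the two hind limbs, with
no active control.  It runs in three steps:

1. Build hind-paw forward trajectories from stride parameters with a
   constant-swing-velocity model (slope = stride length / swing duration
   during swing, zero during stance), the two paws offset by the hind-limb
   alternation phase.
2. Convert the forward offset between the paws into a body-axis angle: the
   perpendicular bisector of the segment connecting the paws makes an angle
   ``theta = atan((x_R - x_L) / w)`` with the anterior-posterior axis, where
   ``w`` is the lateral base width.  A wider base therefore gives *smaller*
   oscillations for the same forward offset.
3. Swing each tail segment and the nose as rigid levers about the
   oscillation center A: segment i at lever arm ``L_i`` has lateral position
   ``S_yi = L_i * sin(theta)``, the nose ``N_y = L * sin(lambda)`` with
   ``lambda`` the angle of the oppositely-directed nose vector, i.e. the
   nose moves in antiphase to the tail.  Each output is finally delayed by a
   fixed time: a base delay for the first tail segment plus an incremental
   per-segment delay following the schedule ``slope * i + intercept`` (ms,
   floored at zero), and a separate nose delay.

Because the delays are fixed *times*, the phase of every segment relative
to the stride grows linearly with cadence (time-locked); with all delays
zero the model is perfectly phase-locked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default per-segment incremental delay schedule, ms per segment index
DELAY_SLOPE_MS = -0.23
DELAY_INTERCEPT_MS = 3.97
#: default base delays fitted from phase-vs-cadence regressions
TAIL_BASE_DELAY_S = 0.031
NOSE_DELAY_S = 0.096


def default_lever_arms(n_segments: int = 15, tail_length_mm: float = 60.0,
                       base_offset_mm: float = 5.0) -> np.ndarray:
    """Evenly spaced lever arms from the oscillation center to each segment."""
    return base_offset_mm + tail_length_mm * np.arange(1, n_segments + 1) / n_segments


@dataclass
class PassiveModelConfig:
    """Geometry and delay schedule of the passive simulator."""

    base_width_mm: float = 25.0
    lever_arms_mm: np.ndarray = field(default_factory=default_lever_arms)
    nose_lever_mm: float = 35.0
    tail_base_delay_s: float = TAIL_BASE_DELAY_S
    nose_delay_s: float = NOSE_DELAY_S
    delay_slope_ms: float = DELAY_SLOPE_MS
    delay_intercept_ms: float = DELAY_INTERCEPT_MS

    def __post_init__(self) -> None:
        self.lever_arms_mm = np.asarray(self.lever_arms_mm, dtype=float)
        if self.base_width_mm <= 0:
            raise ValueError("base width must be positive")
        if np.any(np.diff(self.lever_arms_mm) <= 0):
            raise ValueError("lever arms must increase along the tail")
        if self.tail_base_delay_s < 0 or self.nose_delay_s < 0:
            raise ValueError("delays must be non-negative")

    @property
    def n_segments(self) -> int:
        return len(self.lever_arms_mm)

    def segment_delays_s(self) -> np.ndarray:
        """Total delay of each tail segment.

        The base segment (i=1) carries exactly the base delay; each further
        segment adds the incremental delay ``slope * i + intercept`` ms
        (evaluated at the *preceding* segment index, floored at 0), so the
        increments shrink along the tail.
        """
        i = np.arange(1, self.n_segments)
        incr = np.maximum(self.delay_slope_ms * i + self.delay_intercept_ms, 0.0)
        total = np.concatenate([[0.0], np.cumsum(incr)]) / 1000.0
        return self.tail_base_delay_s + total


@dataclass
class HindPawDrive:
    """Forward hind-paw trajectories driving the passive oscillation."""

    t: np.ndarray                 # s
    x_left: np.ndarray            # mm
    x_right: np.ndarray           # mm
    stride_duration_s: float
    cadence_hz: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def difference(self) -> np.ndarray:
        return self.x_right - self.x_left


def simulate_hind_paws(stride_length_mm: float, swing_duration_s: float,
                       stance_duration_s: float, phase: float,
                       duration_s: float, dt_s: float,
                       t0_s: float = 0.0) -> HindPawDrive:
    """Constant-swing-velocity hind-paw trajectories.

    Each paw advances ``stride_length`` during swing at constant velocity
    (stride length / swing duration) and is stationary during stance; the
    right paw is the left paw shifted by ``phase`` of a stride cycle.
    ``t0_s`` extends the time axis backwards (negative) so that delayed
    readouts have history available.
    """
    if swing_duration_s <= 0 or stance_duration_s <= 0:
        raise ValueError("durations must be positive")
    if not 0 <= phase < 1:
        raise ValueError("phase must lie in [0, 1)")
    if dt_s > swing_duration_s:
        raise ValueError("dt must not exceed the swing duration")
    stride = swing_duration_s + stance_duration_s
    t = np.arange(t0_s, duration_s + dt_s / 2, dt_s)

    def x_of(tt: np.ndarray) -> np.ndarray:
        cycles = np.floor(tt / stride)
        tau = tt - cycles * stride
        # stance first [0, stance), then swing
        in_swing = tau >= stance_duration_s
        swing_progress = np.where(
            in_swing, (tau - stance_duration_s) / swing_duration_s, 0.0)
        return stride_length_mm * (cycles + swing_progress)

    return HindPawDrive(t=t, x_left=x_of(t),
                        x_right=x_of(t - phase * stride),
                        stride_duration_s=stride, cadence_hz=1.0 / stride)


def tail_angle(x_left: np.ndarray, x_right: np.ndarray,
               base_width_mm: float) -> np.ndarray:
    """Body-axis angle of the hind-paw bisector construction.

    ``theta = atan((x_R - x_L) / w)``: zero when the paws are level, 45°
    when their forward offset equals the base width; strictly decreasing in
    magnitude as the base widens.
    """
    if base_width_mm <= 0:
        raise ValueError("base width must be positive")
    return np.arctan((np.asarray(x_right, dtype=float)
                      - np.asarray(x_left, dtype=float)) / base_width_mm)


def _delayed(values: np.ndarray, t: np.ndarray, delay_s: float) -> np.ndarray:
    """Read a signal at ``t - delay``; samples before the recorded history
    are NaN (flagged missing)."""
    out = np.interp(t - delay_s, t, values, left=np.nan, right=np.nan)
    return out


def simulate_passive(config: PassiveModelConfig, drive: HindPawDrive,
                     t_eval: np.ndarray | None = None
                     ) -> dict[str, np.ndarray]:
    """Lateral tail-segment and nose trajectories from a hind-paw drive.

    Returns a dict with ``t`` (evaluation times, by default the drive's
    non-negative times), ``tail`` of shape (n_times, n_segments) with
    ``S_yi(t) = L_i sin(theta(t - D_i))``, and ``nose`` with
    ``N_y(t) = -L sin(theta(t - D_nose))`` (the nose vector is directed
    opposite to the tail vector, so nose and tail base are antiphase at
    equal delay).  Leading samples for which the drive history is too short
    are NaN.
    """
    theta = tail_angle(drive.x_left, drive.x_right, config.base_width_mm)
    if t_eval is None:
        t_eval = drive.t[drive.t >= 0]
    delays = config.segment_delays_s()
    tail = np.empty((len(t_eval), config.n_segments))
    for i in range(config.n_segments):
        th = np.interp(t_eval - delays[i], drive.t, theta,
                       left=np.nan, right=np.nan)
        tail[:, i] = config.lever_arms_mm[i] * np.sin(th)
    th_nose = np.interp(t_eval - config.nose_delay_s, drive.t, theta,
                        left=np.nan, right=np.nan)
    nose = -config.nose_lever_mm * np.sin(th_nose)
    return {"t": np.asarray(t_eval, dtype=float), "tail": tail, "nose": nose,
            "theta": np.interp(t_eval, drive.t, theta)}
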