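"""Parametric synthetic gait generator.

Generates ground-truth 3D feature tracks (four paws, snout, 15 tail
segments, body center) for a mouse trotting along the corridor, together
with the exact stride table they imply.  The generator encodes the
statistical structure the analyses assume:

* stride parameters follow smooth laws of walking speed — cadence and
  stride length increase with speed while stance duration falls steeply —
  with speed = stride length x cadence holding exactly;
* limb phasing is a symmetric trot by default (diagonal pairs synchronous,
  left-right pairs in antiphase); the front-hind phase is configurable so
  that an ataxic-like (pcd-like) front-hind shift can be imposed while
  left-right alternation stays intact;
* paws advance at constant velocity during swing and are stationary during
  stance, with a half-sine vertical lift during swing;
* the tail and nose either oscillate phase-locked to the stride (the
  wildtype-like "rigid" mode: constant phase offset at every speed) or are
  driven by the passive geometric model (the pcd-like "passive" mode:
  constant *time* delays, so phase grows with cadence);
* optional isotropic Gaussian positional noise.

The default coefficients of the speed laws are the package's documented
choices of realistic magnitudes (they produce ~60 mm strides at ~4 Hz
around 0.25 m/s); the laws' functional shapes, not these exact numbers,
carry the scientific content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import PAWS, TAIL_SEGMENTS, MouseMeta, TrackSet
from ..gait import STRIDE_COLUMNS, StrideTable
from ..passive import (HindPawDrive, PassiveModelConfig,
                       default_lever_arms, simulate_passive)


def cadence_law(speed: float, weight_g: float = 20.0) -> float:
    """Stride frequency (1/s) as a function of walking speed (m/s) and body
    size: cadence rises with speed, and a larger animal reaches the same
    speed with longer, less frequent strides (quarter-power size scaling
    around a 20 g reference)."""
    return (2.5 + 7.0 * speed) * (20.0 / weight_g) ** 0.25


def duty_factor_law(speed: float) -> float:
    """Stance fraction of the stride, decreasing with speed."""
    return float(np.clip(0.68 - 0.8 * speed, 0.35, 0.75))


def body_length_mm(weight_g: float) -> float:
    return 55.0 + 1.5 * weight_g


def base_width_mm(weight_g: float) -> float:
    return 14.0 + 0.3 * weight_g


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic trial."""

    speed: float = 0.25              # m/s
    weight_g: float = 20.0
    duty_factor: float | None = None  # None -> speed law
    lr_phase: float = 0.5            # left-right alternation, cycles
    fh_phase: float = 0.0            # front-hind (diagonal) shift, cycles
    vertical_amplitude_mm: float = 3.0
    base_width: float | None = None  # None -> weight law
    tail_mode: str = "rigid"         # "rigid" (phase-locked) | "passive"
    tail_amplitude_mm: float = 8.0   # rigid-mode lateral amplitude at the tip
    nose_amplitude_mm: float = 2.0   # rigid-mode nose amplitude
    noise_sigma_mm: float = 0.0
    fps: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < (self.duty_factor or 0.5) < 1:
            raise ValueError("duty factor must lie in (0, 1)")
        if self.tail_mode not in ("rigid", "passive"):
            raise ValueError("tail_mode must be 'rigid' or 'passive'")

    @property
    def resolved_duty(self) -> float:
        return self.duty_factor if self.duty_factor is not None \
            else duty_factor_law(self.speed)

    @property
    def resolved_base_width(self) -> float:
        return self.base_width if self.base_width is not None \
            else base_width_mm(self.weight_g)


#: phase offset of each paw's stance onset within the cycle, given the
#: left-right and front-hind phases (FR is the reference)
def paw_phases(lr_phase: float, fh_phase: float) -> dict[str, float]:
    return {"FR": 0.0,
            "FL": lr_phase % 1.0,
            "HL": fh_phase % 1.0,
            "HR": (fh_phase + lr_phase) % 1.0}


def _paw_x(t: np.ndarray, stride_len: float, stride_dur: float,
           duty: float, phase: float) -> np.ndarray:
    """Piecewise forward trajectory: stance onset at (k + phase)*T, stance
    for duty*T, then constant-velocity swing."""
    tt = t - phase * stride_dur
    cycles = np.floor(tt / stride_dur + 1e-9)
    tau = tt - cycles * stride_dur
    stance_dur = duty * stride_dur
    swing_dur = stride_dur - stance_dur
    in_swing = tau >= stance_dur - 1e-9
    progress = np.where(in_swing, (tau - stance_dur) / swing_dur, 0.0)
    return stride_len * (cycles + np.clip(progress, 0.0, 1.0))


def _paw_z(t: np.ndarray, stride_dur: float, duty: float, phase: float,
           amplitude: float) -> np.ndarray:
    tt = t - phase * stride_dur
    tau = tt - np.floor(tt / stride_dur + 1e-9) * stride_dur
    stance_dur = duty * stride_dur
    swing_dur = stride_dur - stance_dur
    in_swing = tau >= stance_dur - 1e-9
    progress = np.where(in_swing, (tau - stance_dur) / swing_dur, 0.0)
    return amplitude * np.sin(np.pi * np.clip(progress, 0.0, 1.0)) * in_swing


def gen_gait(spec: SyntheticSpec, duration_s: float = 1.0
             ) -> tuple[TrackSet, StrideTable]:
    """Generate a synthetic trial and its ground-truth stride table.

    Raises when the requested speed is incompatible with a positive swing
    duration under the resolved duty factor.
    """
    rng = np.random.default_rng(spec.seed)
    fps = spec.fps
    # snap the stride period, stance duration and phase offsets to the frame
    # grid so that ground-truth events fall exactly on sampled frames (all
    # analyses are then comparable to truth up to genuine frame quantization)
    n_stride = max(int(round(fps / cadence_law(spec.speed, spec.weight_g))), 4)
    stride_dur = n_stride / fps
    cad = 1.0 / stride_dur
    stride_len = spec.speed * 1000.0 / cad          # mm; speed holds exactly
    n_stance = int(round(spec.resolved_duty * n_stride))
    if not 0 < n_stance < n_stride:
        raise ValueError("speed incompatible with duty/stride constraints")
    duty = n_stance / n_stride
    swing_dur = (1.0 - duty) * stride_dur
    if swing_dur <= 1.0 / fps or stride_len <= 0:
        raise ValueError("speed incompatible with duty/stride constraints")

    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    L = body_length_mm(spec.weight_g)
    w_hind = spec.resolved_base_width
    w_front = 0.8 * w_hind
    phases = {p: round(ph * n_stride) / n_stride
              for p, ph in paw_phases(spec.lr_phase, spec.fh_phase).items()}

    # start with the whole animal (tail tip included) inside the corridor
    x_start = 0.45 * L + 0.8 * L + 10.0
    x_anchor = {"FR": x_start + 0.30 * L, "FL": x_start + 0.30 * L,
                "HR": x_start - 0.10 * L, "HL": x_start - 0.10 * L}
    y_pos = {"FR": w_front / 2, "FL": -w_front / 2,
             "HR": w_hind / 2, "HL": -w_hind / 2}

    features: dict[str, np.ndarray] = {}
    for paw in PAWS:
        # the phase term keeps each paw's *mean* position at its anchor
        # (a later stance onset otherwise shifts the whole trajectory back)
        x = (x_anchor[paw] + phases[paw] * stride_len
             + _paw_x(t, stride_len, stride_dur, duty, phases[paw]))
        y = np.full(n, y_pos[paw])
        z = _paw_z(t, stride_dur, duty, phases[paw], spec.vertical_amplitude_mm)
        features[paw] = np.column_stack([x, y, z])

    body_x = x_start + spec.speed * 1000.0 * t + 0.5 * stride_len
    features["body_center"] = np.column_stack(
        [body_x, np.zeros(n), np.full(n, 15.0)])

    # --- tail and nose ---------------------------------------------------
    lever = default_lever_arms(15, tail_length_mm=0.8 * L)
    if spec.tail_mode == "rigid":
        # phase-locked: the tail rides the hind-limb alternation with a
        # constant *fractional* lag, so its phase relative to the hind-paw
        # difference signal is identical at every speed
        diff = features["HR"][:, 0] - features["HL"][:, 0]
        diff = diff - diff.mean()
        amp = max(np.abs(diff).max(), 1e-9)
        rel = lever / lever[-1]
        tail_y = np.empty((n, 15))
        for i in range(15):
            lag_frames = int(round(0.02 * (i + 1) * n_stride))
            shifted = np.roll(diff, lag_frames)
            shifted[:lag_frames] = shifted[lag_frames] if lag_frames else shifted[0]
            tail_y[:, i] = spec.tail_amplitude_mm * rel[i] * shifted / amp
        nose_y = -spec.nose_amplitude_mm * diff / amp
    else:
        pconf = PassiveModelConfig(
            base_width_mm=w_hind, lever_arms_mm=lever, nose_lever_mm=0.45 * L)
        # drive the model with the *actual* hind-paw trajectories (extended
        # backwards so delayed readouts have history)
        hist = pconf.segment_delays_s().max() + pconf.nose_delay_s + stride_dur
        t_ext = np.arange(-hist, duration_s, 1.0 / fps)
        x_hl = phases["HL"] * stride_len + _paw_x(
            t_ext, stride_len, stride_dur, duty, phases["HL"])
        x_hr = phases["HR"] * stride_len + _paw_x(
            t_ext, stride_len, stride_dur, duty, phases["HR"])
        drive = HindPawDrive(t=t_ext, x_left=x_hl, x_right=x_hr,
                             stride_duration_s=stride_dur, cadence_hz=cad)
        sim = simulate_passive(pconf, drive, t_eval=t)
        tail_y = sim["tail"]
        nose_y = sim["nose"]

    tail_x = body_x[:, None] - 0.45 * L - lever[None, :]
    tail_z = np.maximum(8.0 - 0.4 * lever[None, :] + 0.0 * t[:, None], 1.0)
    for i, name in enumerate(TAIL_SEGMENTS):
        features[name] = np.column_stack(
            [tail_x[:, i], tail_y[:, i], np.broadcast_to(tail_z[:, i], (n,))])

    features["snout"] = np.column_stack(
        [body_x + 0.55 * L, nose_y, np.full(n, 12.0)])

    if spec.noise_sigma_mm > 0:
        for name in features:
            features[name] = features[name] + rng.normal(
                0.0, spec.noise_sigma_mm, features[name].shape)

    meta = MouseMeta(subject_id=f"synthetic_{spec.seed}",
                     weight_g=spec.weight_g, body_length_mm=L)
    tracks = TrackSet(features, fps=fps, trial_id=f"synthetic_{spec.seed}",
                      meta={"spec": spec, "stride_duration": stride_dur,
                            "stride_length": stride_len, "duty_factor": duty})

    # --- ground-truth stride table --------------------------------------
    rows = []
    for paw in PAWS:
        phase = phases[paw]
        k = 0
        while True:
            onset = (k + phase) * stride_dur
            nxt = onset + stride_dur
            if nxt >= duration_s:
                break
            if onset >= 0:
                sw = onset + duty * stride_dur
                rows.append({
                    "paw": paw,
                    "stance_onset": int(round(onset * fps)),
                    "swing_onset": int(round(sw * fps)),
                    "next_stance_onset": int(round(nxt * fps)),
                    "stride_duration": stride_dur,
                    "stance_duration": duty * stride_dur,
                    "swing_duration": swing_dur,
                    "cadence": cad,
                    "stride_length": stride_len,
                    "swing_velocity": stride_len / swing_dur / 1000.0,
                    "peak_swing_velocity": stride_len / swing_dur / 1000.0,
                    "peak_z": spec.vertical_amplitude_mm,
                    "walking_speed": spec.speed,
                })
            k += 1
    truth = StrideTable(pd.DataFrame(rows, columns=STRIDE_COLUMNS),
                        meta=meta, fps=fps)
    return tracks, truth
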