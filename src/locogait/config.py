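"""Run configuration: every tunable constant of the pipeline in one place.

Defaults are the values the tracking and analysis methods were designed
around: transition weight alpha = 0.1, transition allowance 15 px on top of
the bounding-box displacement, location-prior cutoff 0.6 of the normalized
box, cross-view matching tolerance 30% of the detector width, bounding-box
intensity threshold 10%, calibration blob threshold 80%, box-center moving
average of width 5, speed bins of 0.05 m/s with at least 5 strides per bin
per animal, and 400 frames/s acquisition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    # acquisition geometry
    fps: float = 400.0
    px_per_mm: float = 2.17            # full-resolution corridor scale
    view_split_row: int = 100          # first row of the bottom view
    floor_row: int = 95                # side-view row of the corridor floor
    midline_row: int = 150             # bottom-view row of the corridor midline

    # tracking
    alpha: float = 0.1                 # transition weight in the MAP objective
    v_extra: float = 15.0              # px allowance on top of box displacement
    prior_cutoff: float = 0.6          # normalized distance beyond which prior = 0
    prior_eps: float = 0.05            # inverse-distance cap of the prior
    view_tolerance_frac: float = 0.3   # cross-view x tolerance, frac of detector width
    detector_scale: float = 1.0        # scales the canonical detector sizes
    max_paw_candidates: int = 6        # per-frame cap for the joint paw tracker
    bbox_threshold: float = 0.10       # bounding-box intensity threshold
    calib_threshold: float = 0.80      # calibration blob threshold
    box_smooth_width: int = 5          # moving-average width for box centers
    moving_diff_threshold: float = 0.1
    moving_area_fraction: float = 0.1

    # gait segmentation
    stance_velocity_threshold: float = 20.0   # mm/s
    stance_hysteresis_frames: int = 3
    min_phase_frames: int = 5

    # stride statistics
    bin_width: float = 0.05            # m/s
    min_strides_per_bin: int = 5
    n_trajectory_points: int = 100

    seed: int = 0

    def detector_size(self, feature_class: str, view: str) -> tuple[int, int]:
        from .tracking.detect import DETECTOR_SIZES
        h, w = DETECTOR_SIZES[feature_class][view]
        s = self.detector_scale
        return max(int(round(h * s)), 3), max(int(round(w * s)), 3)

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "RunConfig":
        try:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(path_or_text)
        return cls(**data)

    def config_hash(self) -> str:
        """Stable short hash recorded in outputs for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
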