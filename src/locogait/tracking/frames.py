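"""Frame preprocessing: background removal, view calibration, bounding boxes.

The camera records a composite image per frame: the side view of the mouse in
the top part, the bottom view (via a mirror under the glass corridor) below a
horizontal split line.  Preprocessing isolates the mouse from the (static)
corridor and computes a tight per-frame bounding box inside which all feature
detection runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core import BoundingBox, FrameImage

logger = logging.getLogger(__name__)


def subtract_background(frame: FrameImage, background: FrameImage) -> FrameImage:
    """Remove the static corridor by subtracting a pre-session background image.

    The result is clipped at zero so that corridor pixels end up (close to)
    black and only the animal survives.
    """
    if frame.pixels.shape != background.pixels.shape:
        raise ValueError(
            f"frame shape {frame.pixels.shape} != background shape "
            f"{background.pixels.shape}")
    pixels = np.clip(frame.pixels - background.pixels, 0.0, None)
    return FrameImage(pixels=pixels, view_split_row=frame.view_split_row,
                      frame_index=frame.frame_index, timestamp=frame.timestamp)


@dataclass(frozen=True)
class DistortionMap:
    """1D affine map aligning side-view x to bottom-view x: ``x_b = a*x_s + b``."""

    scale: float
    offset: float
    residual_rms: float

    def __call__(self, x_side: np.ndarray | float) -> np.ndarray | float:
        return self.scale * np.asarray(x_side, dtype=float) + self.offset


def estimate_distortion(paired_points: np.ndarray) -> DistortionMap:
    """Fit the side-to-bottom horizontal correction from calibration pairs.

    ``paired_points`` is (n, 2) with columns ``(bottom_x, side_x)`` from a
    calibration object seen in both views; the affine map minimizing the
    squared horizontal mismatch is fitted by least squares.

    Raises
    ------
    ValueError
        For fewer than 3 pairs or a rank-deficient design (all side x equal).
    """
    pts = np.asarray(paired_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("distortion calibration needs at least 3 point pairs")
    bottom_x, side_x = pts[:, 0], pts[:, 1]
    design = np.column_stack([side_x, np.ones_like(side_x)])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("degenerate calibration: side-view x values are constant")
    coef, *_ = np.linalg.lstsq(design, bottom_x, rcond=None)
    resid = bottom_x - design @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return DistortionMap(scale=float(coef[0]), offset=float(coef[1]),
                         residual_rms=rms)


def _frame_extent(pixels: np.ndarray, threshold: float,
                  median_size: int) -> tuple[int, int, int, int] | None:
    """First/last rows and cols with above-threshold pixels after median
    filtering, or None if the frame is empty."""
    mask = pixels > threshold
    if median_size > 1:
        mask = ndimage.median_filter(mask.astype(np.uint8), size=median_size) > 0
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        return None
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window clipped at ends)."""
    half = width // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def compute_bounding_boxes(frames: list[FrameImage] | list[np.ndarray],
                           threshold_frac: float = 0.10,
                           median_size: int = 3,
                           smooth_width: int = 5) -> list[BoundingBox]:
    """Tight, size-stabilized bounding boxes around the mouse.

    Per frame, the raw box spans the first/last rows and columns above
    ``threshold_frac`` of the stack's maximum intensity (after median
    filtering).  A single box size common to all frames is then fixed to
    ``min(mean + 3*SD, max observed)`` per dimension so that occlusion or
    noise spikes cannot inflate it, and the box-center trajectory is smoothed
    with a width-``smooth_width`` moving average.  Frames with no
    above-threshold pixels get their center interpolated from neighbors.
    """
    if not frames:
        raise ValueError("need at least one frame")
    pixel_stack = [getattr(f, "pixels", f) for f in frames]
    global_max = max(float(p.max()) for p in pixel_stack)
    thr = threshold_frac * global_max
    shape = pixel_stack[0].shape

    extents = [_frame_extent(p, thr, median_size) for p in pixel_stack]
    valid = [i for i, e in enumerate(extents) if e is not None]
    if not valid:
        raise ValueError("no frame contains above-threshold pixels")
    if len(valid) < len(frames):
        logger.warning("bounding box: %d empty frame(s), centers interpolated",
                       len(frames) - len(valid))

    heights = np.array([extents[i][1] - extents[i][0] for i in valid], dtype=float)
    widths = np.array([extents[i][3] - extents[i][2] for i in valid], dtype=float)
    box_h = int(round(min(heights.mean() + 3 * heights.std(), heights.max())))
    box_w = int(round(min(widths.mean() + 3 * widths.std(), widths.max())))
    box_h, box_w = max(box_h, 1), max(box_w, 1)

    centers_r = np.full(len(frames), np.nan)
    centers_c = np.full(len(frames), np.nan)
    for i in valid:
        r0, r1, c0, c1 = extents[i]
        centers_r[i] = (r0 + r1 - 1) / 2.0
        centers_c[i] = (c0 + c1 - 1) / 2.0
    idx = np.arange(len(frames), dtype=float)
    for centers in (centers_r, centers_c):
        nan = np.isnan(centers)
        if nan.any():
            centers[nan] = np.interp(idx[nan], idx[~nan], centers[~nan])
    centers_r = _moving_average(centers_r, smooth_width)
    centers_c = _moving_average(centers_c, smooth_width)

    boxes = []
    for cr, cc in zip(centers_r, centers_c):
        r0 = int(round(cr - (box_h - 1) / 2.0))
        c0 = int(round(cc - (box_w - 1) / 2.0))
        r0 = min(max(r0, 0), shape[0] - box_h)
        c0 = min(max(c0, 0), shape[1] - box_w)
        boxes.append(BoundingBox(r0, r0 + box_h, c0, c0 + box_w))
    return boxes
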