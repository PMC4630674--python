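"""End-to-end tracking: composite video frames -> 3D feature tracks in mm.

Order of operations: background subtraction, direction normalization (the
algorithm assumes motion toward increasing columns; frames of left-moving
animals are flipped), bounding boxes, per-view detector scoring + NMS,
cross-view fusion, joint MAP tracking of the four paws on the bottom view,
snout tracking, side-view z tracking given the bottom tracks, per-frame tail
detection, and pixel-to-millimetre conversion.
"""

from __future__ import annotations

import logging

import numpy as np

from ..config import RunConfig
from ..core import (PAWS, TAIL_SEGMENTS, BoundingBox, CandidateGraph,
                    FrameCandidates, FrameImage, TrackSet)
from .detect import LinearDetector, moving_flag, nms_cluster, score_features
from .frames import compute_bounding_boxes, subtract_background
from .fuse import location_prior
from .mtt import track_mtt, track_side_z
from .tail import track_tail_frame

logger = logging.getLogger(__name__)


def _detect_direction(frames: list[FrameImage]) -> int:
    """+1 when the animal moves toward increasing columns."""
    def centroid_col(f: FrameImage) -> float:
        w = f.pixels.sum()
        if w <= 0:
            return np.nan
        return float((f.pixels.sum(axis=0) * np.arange(f.pixels.shape[1])).sum() / w)

    early = centroid_col(frames[0])
    late = centroid_col(frames[-1])
    if not np.isfinite(early) or not np.isfinite(late):
        return 1
    return 1 if late >= early else -1


def _sub_box(box: BoundingBox, row_lo: int, row_hi: int) -> BoundingBox | None:
    r0, r1 = max(box.row_min, row_lo), min(box.row_max, row_hi)
    if r1 <= r0:
        return None
    return BoundingBox(r0, r1, box.col_min, box.col_max)


def _frame_candidates(pixels: np.ndarray, prev_pixels: np.ndarray | None,
                      box: BoundingBox | None, detector: LinearDetector,
                      size: tuple[int, int], conservative: bool,
                      config: RunConfig,
                      row_bounds: tuple[int, int] | None = None
                      ) -> list[tuple[float, float, float, bool]]:
    """Detect one feature class in one view: [(col, row, score, moving)].

    The scored region is the bounding box padded by one detector window
    (clipped to the view's rows), so features hugging the box edge still
    get a full window under them.
    """
    if box is None:
        return []
    h, w = size
    lo, hi = row_bounds if row_bounds is not None else (0, pixels.shape[0])
    box = BoundingBox(max(box.row_min - h, lo), min(box.row_max + h, hi),
                      max(box.col_min - w, 0),
                      min(box.col_max + w, pixels.shape[1]))
    region = pixels[box.row_min:box.row_max, box.col_min:box.col_max]
    smap = score_features(region, detector)
    peaks = nms_cluster(smap, size, conservative=conservative)
    out = []
    for r, c, s in peaks:
        row, col = box.row_min + r, box.col_min + c
        mov = False
        if prev_pixels is not None:
            mov = moving_flag(pixels, prev_pixels, (row, col), size,
                              config.moving_diff_threshold,
                              config.moving_area_fraction)
        out.append((float(col), float(row), float(s), mov))
    return out


def track_video(frames: list[np.ndarray], background: np.ndarray,
                detectors: dict[str, dict[str, LinearDetector]],
                config: RunConfig, flip: str = "auto",
                trial_id: str = "trial") -> TrackSet:
    """Track paws, snout and tail through a composite corridor video.

    Parameters
    ----------
    frames : list of 2D arrays
        Grayscale composite frames (side view above ``config.view_split_row``,
        bottom view below), intensities in [0, 1].
    background : 2D array
        Pre-session corridor image, same shape.
    detectors : mapping feature_class -> view -> LinearDetector
    flip : "auto" | "left" | "right"
        Walking direction; "left" means the animal moves toward decreasing
        columns and frames are mirrored before tracking.
    """
    split = config.view_split_row
    bg = FrameImage(background, split)
    fimgs = [subtract_background(FrameImage(f, split, frame_index=i, timestamp=i / config.fps), bg)
             for i, f in enumerate(frames)]

    if flip == "auto":
        direction = _detect_direction(fimgs)
    else:
        direction = -1 if flip == "left" else 1
    flipped = direction < 0
    if flipped:
        fimgs = [FrameImage(f.pixels[:, ::-1], split, f.frame_index, f.timestamp)
                 for f in fimgs]

    n_frames = len(fimgs)
    width = fimgs[0].pixels.shape[1]
    # per-view bounding boxes: the location priors need the box to hug the
    # animal's silhouette in its own view
    boxes_by_view: dict[str, list[BoundingBox]] = {}
    for view, (lo, hi) in (("side", (0, split)),
                           ("bottom", (split, fimgs[0].pixels.shape[0]))):
        raw = compute_bounding_boxes(
            [f.pixels[lo:hi] for f in fimgs], config.bbox_threshold,
            smooth_width=config.box_smooth_width)
        boxes_by_view[view] = [
            BoundingBox(b.row_min + lo, b.row_max + lo, b.col_min, b.col_max)
            for b in raw]
    centers = np.array([b.center for b in boxes_by_view["bottom"]])
    box_disp = np.linalg.norm(np.diff(centers, axis=0), axis=1)

    # --- detection per frame, class, view -------------------------------
    n_rows = fimgs[0].pixels.shape[0]
    dets: dict[tuple[str, str], list[list[tuple[float, float, float, bool]]]] = {}
    for cls in ("paw", "snout", "tail"):
        for view in ("bottom", "side"):
            size = config.detector_size(cls, view)
            per_frame = []
            bounds = (0, split) if view == "side" else (split, n_rows)
            for t, f in enumerate(fimgs):
                prev = fimgs[t - 1].pixels if t > 0 else None
                per_frame.append(_frame_candidates(
                    f.pixels, prev, boxes_by_view[view][t],
                    detectors[cls][view], size,
                    conservative=(view == "side"), config=config,
                    row_bounds=bounds))
            dets[(cls, view)] = per_frame

    # --- paw tracking: joint MAP over the bottom view -------------------
    paw_graph_frames = []
    cap = config.max_paw_candidates
    for t in range(n_frames):
        cands = sorted(dets[("paw", "bottom")][t], key=lambda c: -c[2])[:cap]
        bbox = boxes_by_view["bottom"][t]
        pos = np.array([(c[0], c[1]) for c in cands]).reshape(-1, 2)
        scores = np.zeros((len(PAWS), len(cands)))
        for j, c in enumerate(cands):
            for o, paw in enumerate(PAWS):
                prior = location_prior((c[0], c[1]), bbox, paw,
                                       cutoff=config.prior_cutoff,
                                       eps=config.prior_eps)
                scores[o, j] = c[2] * prior
        paw_graph_frames.append(FrameCandidates(pos, scores))
    paw_graph = CandidateGraph(paw_graph_frames, alpha=config.alpha,
                               v_base=config.v_extra, box_displacement=box_disp)
    paw_res = track_mtt(paw_graph, n_objects=len(PAWS))

    # --- snout: single-object MAP ---------------------------------------
    snout_frames = []
    for t in range(n_frames):
        cands = dets[("snout", "bottom")][t]
        bbox = boxes_by_view["bottom"][t]
        pos = np.array([(c[0], c[1]) for c in cands]).reshape(-1, 2)
        scores = np.array([[c[2] * location_prior((c[0], c[1]), bbox, "snout",
                                                  cutoff=config.prior_cutoff,
                                                  eps=config.prior_eps)
                            for c in cands]]).reshape(1, -1)
        snout_frames.append(FrameCandidates(pos, scores))
    snout_graph = CandidateGraph(snout_frames, alpha=config.alpha,
                                 v_base=config.v_extra, box_displacement=box_disp)
    snout_res = track_mtt(snout_graph, n_objects=1)

    # --- side-view z given bottom tracks --------------------------------
    def side_frames(cls: str) -> list[FrameCandidates]:
        out = []
        for t in range(n_frames):
            cands = dets[(cls, "side")][t]
            pos = np.array([(c[0], c[1]) for c in cands]).reshape(-1, 2)
            scores = np.array([[c[2] for c in cands]]).reshape(1, -1)
            out.append(FrameCandidates(pos, scores))
        return out

    paw_side = side_frames("paw")
    snout_side = side_frames("snout")
    z_rows: dict[str, np.ndarray] = {}
    for o, paw in enumerate(PAWS):
        rows, _ = track_side_z(paw_res.positions[o, :, 0], paw_side,
                               config.detector_size("paw", "side")[1],
                               alpha=config.alpha, v_base=config.v_extra,
                               box_displacement=box_disp,
                               tolerance_frac=config.view_tolerance_frac)
        z_rows[paw] = rows
    z_rows["snout"], _ = track_side_z(
        snout_res.positions[0, :, 0], snout_side,
        config.detector_size("snout", "side")[1],
        alpha=config.alpha, v_base=config.v_extra, box_displacement=box_disp,
        tolerance_frac=config.view_tolerance_frac)

    # --- tail: per-frame largest cross-view region ----------------------
    tail_px = np.full((n_frames, 15, 3), np.nan)
    for t, f in enumerate(fimgs):
        b_box = boxes_by_view["bottom"][t]
        s_box = boxes_by_view["side"][t]
        b_mask = np.zeros_like(f.pixels, dtype=bool)
        s_mask = np.zeros_like(f.pixels, dtype=bool)
        if b_box is not None:
            region = f.pixels[b_box.row_min:b_box.row_max,
                              b_box.col_min:b_box.col_max]
            smap = score_features(region, detectors["tail"]["bottom"])
            b_mask[b_box.row_min:b_box.row_max,
                   b_box.col_min:b_box.col_max] = np.isfinite(smap) & (smap > 0)
        if s_box is not None:
            region = f.pixels[s_box.row_min:s_box.row_max,
                              s_box.col_min:s_box.col_max]
            smap = score_features(region, detectors["tail"]["side"])
            s_mask[s_box.row_min:s_box.row_max,
                   s_box.col_min:s_box.col_max] = np.isfinite(smap) & (smap > 0)
        tail_px[t] = track_tail_frame(b_mask[split:], s_mask[:split])

    # --- convert pixels to millimetres ----------------------------------
    scale = config.px_per_mm
    y_sign = -1.0 if flipped else 1.0

    def to_mm(col: np.ndarray, row_bottom: np.ndarray,
              row_side: np.ndarray) -> np.ndarray:
        x = (width - 1 - col if flipped else col) / scale
        y = y_sign * (row_bottom - (config.midline_row - split)) / scale
        z = (config.floor_row - row_side) / scale
        return np.column_stack([x, y, z])

    features: dict[str, np.ndarray] = {}
    for o, paw in enumerate(PAWS):
        col = paw_res.positions[o, :, 0]
        row_b = paw_res.positions[o, :, 1]
        gap = ~np.isfinite(col)
        if gap.any() and (~gap).any():
            idx = np.arange(n_frames, dtype=float)
            col, row_b = col.copy(), row_b.copy()
            col[gap] = np.interp(idx[gap], idx[~gap], col[~gap])
            row_b[gap] = np.interp(idx[gap], idx[~gap], row_b[~gap])
        features[paw] = to_mm(col, row_b - split, z_rows[paw])
    features["snout"] = to_mm(snout_res.positions[0, :, 0],
                              snout_res.positions[0, :, 1] - split,
                              z_rows["snout"])
    for i, name in enumerate(TAIL_SEGMENTS):
        features[name] = to_mm(tail_px[:, i, 0], tail_px[:, i, 1],
                               tail_px[:, i, 2])
    paw_xy = np.stack([features[p][:, :2] for p in PAWS])
    bc = np.column_stack([np.nanmean(paw_xy[:, :, 0], axis=0),
                          np.nanmean(paw_xy[:, :, 1], axis=0),
                          np.full(n_frames, np.nan)])
    features["body_center"] = bc

    meta = {"flipped": flipped, "config_hash": config.config_hash()}
    return TrackSet(features, fps=config.fps, px_per_mm=scale,
                    trial_id=trial_id, meta=meta)
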