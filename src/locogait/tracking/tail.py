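"""Per-frame tail detection: largest cross-view-consistent region, split into
15 equidistant segments along the body axis.  The tail is detected
independently in every frame; no temporal linking is applied."""

from __future__ import annotations

import numpy as np
from skimage import measure

N_TAIL_SEGMENTS = 15


def _regions(mask: np.ndarray) -> list[dict]:
    labeled = measure.label(mask, connectivity=2)
    out = []
    for rp in measure.regionprops(labeled):
        r0, c0, r1, c1 = rp.bbox
        out.append({"coords": rp.coords, "area": rp.area,
                    "col_min": c0, "col_max": c1})
    return out


def _x_overlap(a: dict, b: dict) -> float:
    return min(a["col_max"], b["col_max"]) - max(a["col_min"], b["col_min"])


def _segment_positions(region: dict, n: int) -> np.ndarray:
    """(n, 2) of (col, row): region row-centroid sampled at n equidistant
    column stations spanning the region."""
    coords = region["coords"]          # (m, 2) row, col
    cols = np.linspace(region["col_min"], region["col_max"] - 1, n)
    out = np.empty((n, 2))
    for i, c in enumerate(cols):
        sel = np.abs(coords[:, 1] - c) <= 0.5
        if not sel.any():
            nearest = np.argmin(np.abs(coords[:, 1] - c))
            sel = coords[:, 1] == coords[nearest, 1]
        out[i] = (c, coords[sel, 0].mean())
    return out


def track_tail_frame(bottom_mask: np.ndarray, side_mask: np.ndarray,
                     n_segments: int = N_TAIL_SEGMENTS,
                     tail_tip_forward: bool = False) -> np.ndarray:
    """Locate the tail in one frame from thresholded tail-score masks.

    Bottom-view regions are matched to side-view regions by overlap of their
    column (x) extents; among cross-view-consistent pairs the largest region
    is the detection.  Its medial line is sampled at ``n_segments``
    equidistant x stations, segment 1 at the tail base (the forward end
    unless ``tail_tip_forward``).

    Returns (n_segments, 3) of ``(col, row_bottom, row_side)``; all NaN when
    no tail region exists, NaN ``row_side`` when only the bottom view has one.
    """
    out = np.full((n_segments, 3), np.nan)
    bottom_regions = _regions(np.asarray(bottom_mask, dtype=bool))
    if not bottom_regions:
        return out
    side_regions = _regions(np.asarray(side_mask, dtype=bool))

    best, best_side, best_size = None, None, -1.0
    for br in bottom_regions:
        matches = [sr for sr in side_regions if _x_overlap(br, sr) > 0]
        sr = max(matches, key=lambda r: r["area"]) if matches else None
        size = br["area"] + (sr["area"] if sr is not None else 0)
        if size > best_size:
            best, best_side, best_size = br, sr, size

    seg_b = _segment_positions(best, n_segments)
    if not tail_tip_forward:
        seg_b = seg_b[::-1]            # base (segment 1) at the forward end
    out[:, 0] = seg_b[:, 0]
    out[:, 1] = seg_b[:, 1]
    if best_side is not None:
        side_cols = np.linspace(best_side["col_min"], best_side["col_max"] - 1,
                                n_segments)
        coords = best_side["coords"]
        for i, c in enumerate(np.sort(side_cols)):
            sel = np.abs(coords[:, 1] - c) <= 0.5
            if sel.any():
                out_i = np.argmin(np.abs(out[:, 0] - c))
                out[out_i, 2] = coords[sel, 0].mean()
    return out
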