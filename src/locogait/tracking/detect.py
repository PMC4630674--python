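"""Feature detection: linear sliding-window scoring and non-maximum suppression.

Each body feature (paw, snout, tail) in each view has a linear detector — a
weight template plus bias — trained as a linear classifier on labeled image
patches.  Filtering an image with the detector yields a per-pixel score map;
non-maximum suppression reduces it to a small set of candidate locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: detector window sizes (rows, cols) in full-resolution pixels, per view
DETECTOR_SIZES: dict[str, dict[str, tuple[int, int]]] = {
    "paw":   {"bottom": (30, 30), "side": (20, 30)},
    "snout": {"bottom": (40, 40), "side": (20, 40)},
    "tail":  {"bottom": (30, 30), "side": (25, 30)},
}


@dataclass
class LinearDetector:
    """Linear sliding-window detector: score = <weights, patch> + bias."""

    feature_class: str
    view: str
    weights: np.ndarray        # 2D template, shape = detector size
    bias: float

    @property
    def size(self) -> tuple[int, int]:
        return self.weights.shape


def train_detector(patches: np.ndarray, labels: np.ndarray,
                   feature_class: str, view: str,
                   C: float = 1.0) -> LinearDetector:
    """Fit a linear classifier on labeled patches and wrap it as a detector.

    ``patches`` is (n, h, w); ``labels`` is binary (1 = feature present).
    A linear SVM gives the maximum-margin hyperplane whose normal vector,
    reshaped to (h, w), is the scoring template.
    """
    from sklearn.svm import LinearSVC

    patches = np.asarray(patches, dtype=float)
    n, h, w = patches.shape
    clf = LinearSVC(C=C, loss="squared_hinge", max_iter=20000)
    clf.fit(patches.reshape(n, h * w), np.asarray(labels).astype(int))
    return LinearDetector(feature_class=feature_class, view=view,
                          weights=clf.coef_.reshape(h, w),
                          bias=float(clf.intercept_[0]))


def score_features(region: np.ndarray, detector: LinearDetector) -> np.ndarray:
    """Slide the detector over ``region`` and return a per-pixel score map.

    The map has the region's shape; each entry is the score of the detector
    window centered at that pixel.  Pixels whose window does not fit entirely
    inside the region are set to ``-inf``.  A region smaller than the
    detector yields an all ``-inf`` (empty) map.
    """
    region = np.asarray(region, dtype=float)
    h, w = detector.size
    out = np.full(region.shape, -np.inf)
    if region.shape[0] < h or region.shape[1] < w:
        return out
    valid = signal.fftconvolve(region, detector.weights[::-1, ::-1], mode="valid")
    valid = valid + detector.bias
    r0, c0 = (h - 1) // 2, (w - 1) // 2
    out[r0:r0 + valid.shape[0], c0:c0 + valid.shape[1]] = valid
    return out


def nms_cluster(score_map: np.ndarray, detector_size: tuple[int, int],
                conservative: bool = False,
                score_threshold: float = 0.0) -> list[tuple[int, int, float]]:
    """Cluster positively classified pixels into isolated local maxima.

    Candidates are pixels above ``score_threshold``, accepted greedily in
    order of decreasing score (ties to the smallest ``(row, col)``) with the
    constraint that accepted candidates are separated by at least the
    suppression radius.  The default radius is half the detector window per
    axis — the window itself spans two to three feature diameters, and
    suppressing over the full window merges paws that approach within a paw
    length of each other (front and hind paws do, every stride).  The
    conservative variant (used on the side view, where features overlap
    heavily) halves the radius again and therefore returns more candidates.

    Returns a list of ``(row, col, score)``.
    """
    score_map = np.asarray(score_map, dtype=float)
    mask = np.isfinite(score_map) & (score_map > score_threshold)
    if not mask.any():
        return []
    rows, cols = np.nonzero(mask)
    scores = score_map[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    divisor = 4 if conservative else 2
    radius_r = max(detector_size[0] // divisor, 1)
    radius_c = max(detector_size[1] // divisor, 1)

    kept_r: list[int] = []
    kept_c: list[int] = []
    out: list[tuple[int, int, float]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if any(abs(r - kr) < radius_r and abs(c - kc) < radius_c
               for kr, kc in zip(kept_r, kept_c)):
            continue
        kept_r.append(r)
        kept_c.append(c)
        out.append((r, c, float(scores[i])))
    return out


def moving_flag(current: np.ndarray, previous: np.ndarray,
                position: tuple[int, int], detector_size: tuple[int, int],
                diff_threshold: float = 0.1,
                area_fraction: float = 0.1) -> bool:
    """Classify a candidate as moving from the frame difference.

    Counts pixels inside the candidate's detector box whose absolute
    intensity change from the previous frame exceeds ``diff_threshold``; the
    candidate is moving when they cover more than ``area_fraction`` of the
    box area.
    """
    r, c = position
    h, w = detector_size
    r0, c0 = max(r - h // 2, 0), max(c - w // 2, 0)
    r1 = min(r0 + h, current.shape[0])
    c1 = min(c0 + w, current.shape[1])
    if r1 <= r0 or c1 <= c0:
        return False
    diff = np.abs(current[r0:r1, c0:c1] - previous[r0:r1, c0:c1])
    return float(np.mean(diff > diff_threshold)) > area_fraction
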