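"""Rendered corridor-video fixtures with per-frame ground truth.

Emulates the composite imaging geometry of the corridor setup: a side view
of the animal in the upper part of each frame and, below a horizontal split
line, the bottom view through the glass floor (via a mirror), sharing the
horizontal (forward) axis.  The mouse is drawn as a body ellipse with
brighter paw discs, a snout disc and a tail polyline in both views; the
renderer returns the exact feature positions it drew, so tracking output
can be scored against ground truth to sub-pixel precision.

The default layout is a quarter-resolution corridor (360 px wide) that
keeps end-to-end tests fast; the full-resolution geometry is just a matter
of scaling the layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse, line

from ..core import PAWS, TAIL_SEGMENTS, TrackSet

logger = logging.getLogger(__name__)


@dataclass
class FixtureLayout:
    """Projection geometry of the rendered composite video."""

    width_px: int = 360
    side_height_px: int = 40
    bottom_height_px: int = 64
    px_per_mm: float = 0.545          # quarter-resolution corridor scale
    floor_offset_px: int = 4          # floor this far above the split line
    body_intensity: float = 0.45
    paw_intensity: float = 1.0
    snout_intensity: float = 0.85
    tail_intensity: float = 0.7
    paw_radius_mm: float = 4.0
    snout_radius_mm: float = 5.5
    tail_radius_mm: float = 2.5
    background_level: float = 0.0

    @property
    def view_split_row(self) -> int:
        return self.side_height_px

    @property
    def floor_row(self) -> int:
        return self.side_height_px - self.floor_offset_px

    @property
    def midline_row(self) -> int:
        return self.side_height_px + self.bottom_height_px // 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.side_height_px + self.bottom_height_px, self.width_px)

    def bottom_rc(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        """Composite (row, col) of a bottom-view point."""
        return (self.midline_row + y_mm * self.px_per_mm,
                x_mm * self.px_per_mm)

    def side_rc(self, x_mm: float, z_mm: float) -> tuple[float, float]:
        return (self.floor_row - z_mm * self.px_per_mm,
                x_mm * self.px_per_mm)


@dataclass
class FixtureVideo:
    """A rendered trial: frames plus the ground truth used to draw them."""

    frames: list[np.ndarray]
    background: np.ndarray
    layout: FixtureLayout
    fps: float
    truth_bottom: dict[str, np.ndarray]   # feature -> (n_frames, 2) (row, col)
    truth_side: dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _draw_disk(img: np.ndarray, rc: tuple[float, float], radius: float,
               value: float) -> bool:
    rr, cc = disk(rc, radius, shape=img.shape)
    if rr.size == 0:
        return False
    img[rr, cc] = np.maximum(img[rr, cc], value)
    return True


def render_fixture(tracks: TrackSet, layout: FixtureLayout | None = None
                   ) -> FixtureVideo:
    """Render ground-truth tracks into a composite corridor video.

    Features whose projection falls outside the frame are clipped and
    flagged with a warning.  The returned ground truth is in composite
    (row, col) pixel coordinates for each view.
    """
    layout = layout or FixtureLayout()
    s = layout.px_per_mm
    n = tracks.n_frames
    shape = layout.shape
    background = np.full(shape, layout.background_level)

    truth_bottom = {f: np.full((n, 2), np.nan) for f in tracks.feature_names}
    truth_side = {f: np.full((n, 2), np.nan) for f in tracks.feature_names}
    frames = []
    clipped = 0

    body_len = tracks.meta.get("body_length_mm",
                               getattr(tracks.meta.get("spec"), "weight_g", 20.0)
                               * 1.5 + 55.0)

    for f in range(n):
        img = background.copy()
        bx = tracks.body_center_x()[f] if "body_center" not in tracks \
            else tracks.x("body_center")[f]
        by = tracks.y("body_center")[f] if "body_center" in tracks else 0.0
        bz = tracks.z("body_center")[f] if "body_center" in tracks else 15.0
        if not np.isfinite(bz):
            bz = 15.0

        # body ellipse, bottom view
        r0, c0 = layout.bottom_rc(bx, by)
        rr, cc = ellipse(r0, c0, 11.0 * s, 0.42 * body_len * s, shape=shape)
        img[rr, cc] = np.maximum(img[rr, cc], layout.body_intensity)
        # body ellipse, side view
        r1, c1 = layout.side_rc(bx, bz)
        rr, cc = ellipse(r1, c1, 9.0 * s, 0.42 * body_len * s, shape=shape)
        img[rr, cc] = np.maximum(img[rr, cc], layout.body_intensity)

        # tail polyline (under the paws/snout in draw order)
        prev_b = prev_s = None
        for name in TAIL_SEGMENTS:
            x, y, z = tracks[name][f]
            if not np.isfinite(x):
                continue
            rb = layout.bottom_rc(x, y)
            rs = layout.side_rc(x, z if np.isfinite(z) else 5.0)
            for rc, prev, truth in ((rb, prev_b, truth_bottom),
                                    (rs, prev_s, truth_side)):
                _draw_disk(img, rc, layout.tail_radius_mm * s,
                           layout.tail_intensity)
                if prev is not None:
                    rr, cc = line(int(round(prev[0])), int(round(prev[1])),
                                  int(round(rc[0])), int(round(rc[1])))
                    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                    img[rr[ok], cc[ok]] = np.maximum(
                        img[rr[ok], cc[ok]], layout.tail_intensity)
                truth[name][f] = rc
            prev_b, prev_s = rb, rs

        # paws
        for name in PAWS:
            x, y, z = tracks[name][f]
            rb = layout.bottom_rc(x, y)
            rs = layout.side_rc(x, max(z, 0.0) if np.isfinite(z) else 0.0)
            ok_b = _draw_disk(img, rb, layout.paw_radius_mm * s,
                              layout.paw_intensity)
            ok_s = _draw_disk(img, rs, 0.7 * layout.paw_radius_mm * s,
                              layout.paw_intensity)
            if not (ok_b and ok_s):
                clipped += 1
            truth_bottom[name][f] = rb
            truth_side[name][f] = rs

        # snout
        x, y, z = tracks["snout"][f]
        rb = layout.bottom_rc(x, y)
        rs = layout.side_rc(x, z if np.isfinite(z) else 12.0)
        _draw_disk(img, rb, layout.snout_radius_mm * s, layout.snout_intensity)
        _draw_disk(img, rs, 0.8 * layout.snout_radius_mm * s,
                   layout.snout_intensity)
        truth_bottom["snout"][f] = rb
        truth_side["snout"][f] = rs

        frames.append(np.clip(img, 0.0, 1.0))

    if clipped:
        logger.warning("%d feature projections clipped at the frame edge", clipped)
    return FixtureVideo(frames=frames, background=background, layout=layout,
                        fps=tracks.fps, truth_bottom=truth_bottom,
                        truth_side=truth_side)


# ---------------------------------------------------------------------------
# labeled patches for detector training
# ---------------------------------------------------------------------------

def _extract_patch(img: np.ndarray, rc: tuple[float, float],
                   size: tuple[int, int]) -> np.ndarray | None:
    h, w = size
    r0 = int(round(rc[0])) - h // 2
    c0 = int(round(rc[1])) - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        return None
    return img[r0:r0 + h, c0:c0 + w]


def labeled_patches(video: FixtureVideo, feature_class: str, view: str,
                    size: tuple[int, int], n_negative_per_frame: int = 10,
                    rng: np.random.Generator | None = None,
                    frame_stride: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative training patches from a rendered fixture.

    Positives are windows centered on the true feature positions; negatives
    are windows centered on the *other* feature classes (hard negatives, so
    e.g. the paw detector learns not to fire on the snout) plus windows at
    random locations at least half a window away from every positive of the
    class.  Returns ``(patches, labels)``.
    """
    rng = rng or np.random.default_rng(0)
    class_names = {"paw": list(PAWS), "snout": ["snout"],
                   "tail": list(TAIL_SEGMENTS)}
    names = class_names[feature_class]
    other_names = [nm for cls, nms in class_names.items() if cls != feature_class
                   for nm in (nms if cls != "tail" else nms[::5])]
    truth = video.truth_bottom if view == "bottom" else video.truth_side
    h, w = size
    patches, labels = [], []
    for f in range(0, video.n_frames, frame_stride):
        img = video.frames[f]
        pos_rc = [truth[nm][f] for nm in names if np.isfinite(truth[nm][f]).all()]
        for rc in pos_rc:
            p = _extract_patch(img, rc, size)
            if p is not None:
                patches.append(p)
                labels.append(1)
        for nm in other_names:
            rc = truth[nm][f]
            if not np.isfinite(rc).all():
                continue
            # the center plus small offsets: the detector must reject the
            # whole neighborhood of a wrong feature, not just its center
            for dr, dc in ((0, 0), (-2, 0), (2, 0), (0, -2), (0, 2),
                           (-3, 0), (3, 0), (0, -3), (0, 3),
                           (-2, -2), (-2, 2), (2, -2), (2, 2)):
                rr, cc = rc[0] + dr, rc[1] + dc
                if any(abs(rr - pr) < h / 2 and abs(cc - pc) < w / 2
                       for pr, pc in pos_rc):
                    continue
                p = _extract_patch(img, (rr, cc), size)
                if p is not None:
                    patches.append(p)
                    labels.append(0)
        # silhouette-boundary negatives: the detector must not fire on the
        # body outline, which otherwise yields paw-like edge blobs
        from scipy import ndimage as _ndi
        fg = img > 0.05
        boundary = fg & ~_ndi.binary_erosion(fg, iterations=2)
        brows, bcols = np.nonzero(boundary)
        if brows.size:
            pick = rng.choice(brows.size, size=min(15, brows.size),
                              replace=False)
            for r, c in zip(brows[pick], bcols[pick]):
                if any(abs(r - pr) < h / 2 and abs(c - pc) < w / 2
                       for pr, pc in pos_rc):
                    continue
                p = _extract_patch(img, (float(r), float(c)), size)
                if p is not None:
                    patches.append(p)
                    labels.append(0)
        tries = 0
        added = 0
        while added < n_negative_per_frame and tries < 50 * n_negative_per_frame:
            tries += 1
            r = rng.uniform(h / 2, img.shape[0] - h / 2)
            c = rng.uniform(w / 2, img.shape[1] - w / 2)
            if any(abs(r - pr) < h / 2 and abs(c - pc) < w / 2
                   for pr, pc in pos_rc):
                continue
            p = _extract_patch(img, (r, c), size)
            if p is not None:
                patches.append(p)
                labels.append(0)
                added += 1
    return np.array(patches), np.array(labels)


def train_fixture_detectors(video: FixtureVideo, config) -> dict:
    """Train the six linear detectors (3 classes x 2 views) on one fixture."""
    from ..tracking.detect import train_detector

    rng = np.random.default_rng(config.seed)
    detectors: dict[str, dict] = {}
    for cls in ("paw", "snout", "tail"):
        detectors[cls] = {}
        for view in ("bottom", "side"):
            size = config.detector_size(cls, view)
            patches, labels = labeled_patches(video, cls, view, size, rng=rng)
            detectors[cls][view] = train_detector(patches, labels, cls, view)
    return detectors
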