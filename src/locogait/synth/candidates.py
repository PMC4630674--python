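"""Synthetic candidate graphs: a controlled test harness for the tracker.

Turns ground-truth tracks into per-frame detection candidates with the
failure modes of a real detector — positional jitter, missed detections
(dropout) and clutter (false positives) — while retaining the true
assignment, so tracking accuracy can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..core import PAWS, BoundingBox, CandidateGraph, FrameCandidates, TrackSet
from ..tracking.fuse import location_prior

logger = logging.getLogger(__name__)


@dataclass
class CandidateTruth:
    """True candidate index per object per frame (-1 where dropped out)."""

    assignment: np.ndarray       # (n_objects, n_frames)
    object_names: list[str]


def gen_candidates(tracks: TrackSet, clutter_rate: float = 0.0,
                   dropout_prob: float = 0.0, jitter_px: float = 0.0,
                   seed: int = 0, px_per_mm: float = 1.0,
                   score_true: float = 1.0, score_clutter: float = 0.4,
                   objects: tuple[str, ...] = PAWS,
                   use_priors: bool = True) -> tuple[CandidateGraph, CandidateTruth]:
    """Build a candidate graph for the paw tracker from ground-truth tracks.

    Per frame: each object's true position (in px, bottom view) becomes a
    high-score candidate with isotropic Gaussian jitter, dropped with
    probability ``dropout_prob``; Poisson(``clutter_rate``) clutter
    candidates with lower scores are scattered uniformly over the paw
    bounding region.  With ``use_priors`` the per-object score rows are
    weighted by the paw-identity location prior (otherwise all objects see
    identical scores).  Scores get a tiny deterministic perturbation so that
    optima are unique.
    """
    rng = np.random.default_rng(seed)
    n_frames = tracks.n_frames
    n_obj = len(objects)
    frames: list[FrameCandidates] = []
    assignment = np.full((n_obj, n_frames), -1, dtype=np.int64)
    all_dropped = True

    for f in range(n_frames):
        true_xy = np.array([[tracks.x(o)[f] * px_per_mm,
                             tracks.y(o)[f] * px_per_mm] for o in objects])
        span = max(true_xy[:, 0].max() - true_xy[:, 0].min(), 1.0)
        lat = max(true_xy[:, 1].max() - true_xy[:, 1].min(), 1.0)
        margin = 0.25 * max(span, lat)
        lo = true_xy.min(axis=0) - margin
        hi = true_xy.max(axis=0) + margin

        positions, base_scores, kinds = [], [], []
        for o in range(n_obj):
            if rng.uniform() < dropout_prob:
                continue
            positions.append(true_xy[o] + rng.normal(0.0, jitter_px, 2))
            base_scores.append(score_true + 0.01 * rng.standard_normal())
            kinds.append(o)
        n_clutter = rng.poisson(clutter_rate)
        for _ in range(n_clutter):
            positions.append(rng.uniform(lo, hi))
            base_scores.append(score_clutter + 0.01 * rng.standard_normal())
            kinds.append(-1)

        positions = np.array(positions).reshape(-1, 2)
        base_scores = np.array(base_scores)
        if use_priors and positions.shape[0]:
            box = BoundingBox(int(np.floor(lo[1])), int(np.ceil(hi[1])) + 2,
                              int(np.floor(lo[0])), int(np.ceil(hi[0])) + 2)
            scores = np.zeros((n_obj, positions.shape[0]))
            for j, (px, py) in enumerate(positions):
                for o, name in enumerate(objects):
                    fid = name if name in PAWS else "snout"
                    scores[o, j] = base_scores[j] * location_prior(
                        (px, py), box, fid)
        else:
            scores = np.tile(base_scores, (n_obj, 1))

        for j, k in enumerate(kinds):
            if k >= 0:
                assignment[k, f] = j
                all_dropped = False
        frames.append(FrameCandidates(positions, scores))

    if all_dropped:
        logger.warning("all candidates dropped out: graph contains only gaps")
    graph = CandidateGraph(frames=frames)
    return graph, CandidateTruth(assignment=assignment,
                                 object_names=list(objects))


def random_mtt_instance(rng: np.random.Generator,
                        max_objects: int = 4, max_frames: int = 6,
                        max_candidates: int = 5,
                        max_joint_paths: int = 20_000
                        ) -> tuple[CandidateGraph, int]:
    """A random small tracking instance sized for exhaustive verification.

    Draws objects, frames and per-frame candidate counts uniformly within
    the given caps, resampling until the number of joint assignment paths is
    small enough for brute-force enumeration.  Positions are uniform on a
    100 px square, scores uniform on [0, 1]; alpha and the displacement
    limit are drawn so that both loose and binding feasibility constraints
    occur.
    """
    from ..tracking.mtt import _n_states

    while True:
        n_obj = int(rng.integers(1, max_objects + 1))
        n_frames = int(rng.integers(1, max_frames + 1))
        counts = rng.integers(max(n_obj - 1, 1), max_candidates + 1,
                              size=n_frames)
        total = 1.0
        for c in counts:
            total *= _n_states(n_obj, int(c))
        if total <= max_joint_paths:
            break
    frames = []
    for c in counts:
        pos = rng.uniform(0, 100, size=(int(c), 2))
        scores = rng.uniform(0.0, 1.0, size=(n_obj, int(c)))
        frames.append(FrameCandidates(pos, scores))
    alpha = float(rng.choice([0.0, 0.1, 1.0]))
    v_base = float(rng.choice([20.0, 60.0, 200.0]))
    return CandidateGraph(frames=frames, alpha=alpha, v_base=v_base), n_obj
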