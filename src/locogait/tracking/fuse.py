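"""Cross-view candidate fusion and paw-identity location priors."""

from __future__ import annotations

import math
from dataclasses import dataclass
from ..core import BoundingBox, Candidate

#: normalized-box corner (u_forward, u_lateral) assigned to each paw identity.
#: u_forward: 0 = rear of box, 1 = front (direction of motion);
#: u_lateral: 0 = animal's left edge, 1 = animal's right edge.
PAW_CORNERS: dict[str, tuple[float, float]] = {
    "FR": (1.0, 1.0),
    "FL": (1.0, 0.0),
    "HR": (0.0, 1.0),
    "HL": (0.0, 0.0),
}

#: snout anchors to the front edge, mid-lateral
SNOUT_ANCHOR: tuple[float, float] = (1.0, 0.5)


@dataclass
class Candidate3D:
    """A fused bottom+side candidate: full (col, row_bottom, row_side)."""

    bottom: Candidate
    side: Candidate | None      # None when no side match (z unknown)

    @property
    def col(self) -> float:
        return self.bottom.position[0]

    @property
    def row_bottom(self) -> float:
        return self.bottom.position[1]

    @property
    def row_side(self) -> float | None:
        return None if self.side is None else self.side.position[1]

    @property
    def score(self) -> float:
        return self.bottom.score


def match_views(bottom: list[Candidate], side: list[Candidate],
                detector_width: int,
                tolerance_frac: float = 0.3) -> list[Candidate3D]:
    """Fuse bottom- and side-view candidates along the shared horizontal axis.

    A side candidate matches a bottom candidate when their horizontal
    positions agree within ``tolerance_frac`` of the detector width.  Each
    side candidate is assigned to at most one bottom candidate (the nearest
    in x); one bottom candidate may collect several side matches.  When two
    bottom candidates are equidistant, the one whose moving/not-moving flag
    agrees with the side candidate wins; if that does not disambiguate, both
    pairings are retained.  Bottom candidates without any side match are kept
    with an unknown z.
    """
    tol = tolerance_frac * detector_width
    out: list[Candidate3D] = []
    matched_bottom: dict[int, list[Candidate]] = {i: [] for i in range(len(bottom))}

    for s in side:
        dists = [abs(b.position[0] - s.position[0]) for b in bottom]
        within = [i for i, d in enumerate(dists) if d <= tol]
        if not within:
            continue
        dmin = min(dists[i] for i in within)
        best = [i for i in within if math.isclose(dists[i], dmin)]
        if len(best) > 1:
            agree = [i for i in best if bottom[i].moving == s.moving]
            if len(agree) >= 1:
                best = agree
        # unresolved ambiguity: retain the pairing with every tied candidate
        for i in best:
            matched_bottom[i].append(s)

    for i, b in enumerate(bottom):
        sides = matched_bottom[i]
        if not sides:
            out.append(Candidate3D(bottom=b, side=None))
        else:
            for s in sides:
                out.append(Candidate3D(bottom=b, side=s))
    return out


def location_prior(position: tuple[float, float], box: BoundingBox,
                   feature_id: str, direction: int = 1,
                   cutoff: float = 0.6, eps: float = 0.05) -> float:
    """Prior weight distinguishing paw identities inside the bounding box.

    The bounding box is normalized to the unit square and each paw identity
    is anchored to "its" corner (the front-right paw to the front-right
    corner, and so on); the prior is the inverse distance ``1/(d + eps)`` to
    that corner, zeroed beyond a normalized distance of ``cutoff``.
    ``direction`` is +1 when the animal moves toward increasing columns.
    Bottom-view convention: larger row = animal's right.
    """
    col, row = position
    u_fwd = (col - box.col_min) / max(box.width - 1, 1)
    u_lat = (row - box.row_min) / max(box.height - 1, 1)
    if direction < 0:
        u_fwd = 1.0 - u_fwd
        u_lat = 1.0 - u_lat
    if feature_id == "snout":
        anchor = SNOUT_ANCHOR
    else:
        anchor = PAW_CORNERS[feature_id]
    d = math.hypot(u_fwd - anchor[0], u_lat - anchor[1])
    if d > cutoff:
        return 0.0
    return 1.0 / (d + eps)
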