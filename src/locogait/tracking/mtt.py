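"""MAP multi-target tracking over per-frame candidate locations.

Tracking is cast as maximum a posteriori estimation over a chain of candidate
locations: choose, for every object ``o`` and frame ``t``, a candidate
``x_{o,t}`` (or a gap) maximizing

    C(x) = sum_o [ sum_t U(x_{o,t}) + alpha * sum_t P(x_{o,t}, x_{o,t+1}) ]

where ``U`` is the prior-weighted detection score, ``P(p, q) = 1/(1 + |p-q|)``
the inverse image distance, and ``alpha`` the relative weight of transitions
(default 0.1).  Transitions longer than the per-frame limit ``v`` (bounding
box displacement plus a fixed 15 px allowance) are infeasible, and no two
objects may occupy the same candidate in the same frame.

The exclusivity constraint couples the objects, so the optimum is found by
exact dynamic programming over *joint* assignments: the per-frame state is an
injective partial map from objects to candidates (a gap is allowed and
carries zero detection score and no transition score).  Ties are broken
lexicographically by candidate index, gaps ordering first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np

from ..core import CandidateGraph, FrameCandidates

logger = logging.getLogger(__name__)

GAP = -1

#: refuse to build joint-state spaces larger than this; candidates are
#: trimmed to the top-scoring subset instead
_MAX_STATES = 20_000


def inverse_distance_score(d: np.ndarray | float) -> np.ndarray | float:
    """Transition affinity P = 1/(1 + d); finite at zero displacement."""
    return 1.0 / (1.0 + d)


def _enumerate_states(n_objects: int, n_candidates: int) -> np.ndarray:
    """All injective partial maps objects -> candidates ∪ {gap}, in
    lexicographic order with the gap (-1) sorting first."""
    states: list[tuple[int, ...]] = []

    def rec(prefix: list[int]) -> None:
        if len(prefix) == n_objects:
            states.append(tuple(prefix))
            return
        for v in range(-1, n_candidates):
            if v >= 0 and v in prefix:
                continue
            prefix.append(v)
            rec(prefix)
            prefix.pop()

    rec([])
    return np.array(states, dtype=np.int64).reshape(len(states), n_objects)


def _n_states(n_objects: int, n_candidates: int) -> int:
    total = 0
    for k in range(n_objects + 1):
        # choose which objects are assigned, then an ordered candidate subset
        n_perm = 1
        for j in range(k):
            n_perm *= (n_candidates - j)
        from math import comb
        total += comb(n_objects, k) * n_perm
    return total


def _trim_candidates(frame: FrameCandidates, n_objects: int) -> tuple[FrameCandidates, np.ndarray]:
    """Keep the best candidates so the joint state space stays tractable."""
    n = frame.n_candidates
    keep = n
    while keep > n_objects and _n_states(n_objects, keep) > _MAX_STATES:
        keep -= 1
    if keep == n:
        return frame, np.arange(n)
    order = np.argsort(-frame.scores.max(axis=0), kind="stable")[:keep]
    order = np.sort(order)
    logger.warning("trimming frame candidates %d -> %d for tractability", n, keep)
    return FrameCandidates(frame.positions[order], frame.scores[:, order]), order


@dataclass
class MttResult:
    """Optimal joint tracks: candidate index per object per frame (-1 = gap)."""

    assignment: np.ndarray      # (n_objects, n_frames) int
    objective: float
    positions: np.ndarray       # (n_objects, n_frames, 2) float, NaN at gaps


def track_mtt(graph: CandidateGraph, n_objects: int | None = None) -> MttResult:
    """Exact MAP tracking of ``n_objects`` through a candidate graph.

    Returns the argmax of the tracking objective together with its value.
    Frames in which an object has no feasible candidate are bridged as gaps
    (zero detection score, no transition score); a warning is logged when
    the optimum leaves an object unassigned in a frame that had candidates.
    """
    if graph.n_frames < 1:
        raise ValueError("candidate graph must contain at least one frame")
    if n_objects is None:
        n_objects = graph.n_objects
    if n_objects < 1:
        raise ValueError("need at least one object to track")

    frames: list[FrameCandidates] = []
    index_maps: list[np.ndarray] = []
    for f in graph.frames:
        if f.scores.shape[0] not in (1, n_objects):
            raise ValueError("per-frame scores must have one row per object")
        scores = f.scores if f.scores.shape[0] == n_objects else \
            np.repeat(f.scores, n_objects, axis=0)
        trimmed, kept = _trim_candidates(
            FrameCandidates(f.positions, scores), n_objects)
        frames.append(trimmed)
        index_maps.append(kept)

    state_cache: dict[int, np.ndarray] = {}

    def states_for(n_cand: int) -> np.ndarray:
        if n_cand not in state_cache:
            state_cache[n_cand] = _enumerate_states(n_objects, n_cand)
        return state_cache[n_cand]

    def state_scores(frame: FrameCandidates, states: np.ndarray) -> np.ndarray:
        c = frame.n_candidates
        u_ext = np.concatenate([frame.scores, np.zeros((n_objects, 1))], axis=1)
        ext = np.where(states < 0, c, states)
        obj_idx = np.arange(n_objects)
        return u_ext[obj_idx[None, :], ext].sum(axis=1)

    states_prev = states_for(frames[0].n_candidates)
    dp = state_scores(frames[0], states_prev)
    pointers: list[np.ndarray] = []

    for t in range(1, graph.n_frames):
        prev_f, cur_f = frames[t - 1], frames[t]
        states_cur = states_for(cur_f.n_candidates)
        cp, cc = prev_f.n_candidates, cur_f.n_candidates

        d = np.linalg.norm(
            prev_f.positions[:, None, :] - cur_f.positions[None, :, :], axis=2)
        m = np.where(d <= graph.v_limit(t - 1),
                     graph.alpha * inverse_distance_score(d), -np.inf)
        # gap row/column: entering or leaving a gap scores zero
        m_ext = np.full((cp + 1, cc + 1), 0.0)
        m_ext[:cp, :cc] = m

        ext_prev = np.where(states_prev < 0, cp, states_prev)
        ext_cur = np.where(states_cur < 0, cc, states_cur)
        trans = np.zeros((len(states_prev), len(states_cur)))
        for o in range(n_objects):
            trans += m_ext[ext_prev[:, o][:, None], ext_cur[:, o][None, :]]

        best = dp[:, None] + trans
        ptr = best.argmax(axis=0)               # first max = lexicographic tie-break
        dp = state_scores(cur_f, states_cur) + best[ptr, np.arange(len(states_cur))]
        pointers.append(ptr)
        states_prev = states_cur

    end = int(np.argmax(dp))
    objective = float(dp[end])

    # backtrack
    path = [end]
    for ptr in reversed(pointers):
        path.append(int(ptr[path[-1]]))
    path.reverse()

    assignment = np.full((n_objects, graph.n_frames), GAP, dtype=np.int64)
    positions = np.full((n_objects, graph.n_frames, 2), np.nan)
    for t, s_idx in enumerate(path):
        st = states_for(frames[t].n_candidates)[s_idx]
        for o in range(n_objects):
            if st[o] >= 0:
                assignment[o, t] = index_maps[t][st[o]]
                positions[o, t] = frames[t].positions[st[o]]

    n_gaps = int((assignment == GAP).sum())
    if n_gaps and any(f.n_candidates > 0 for f in frames):
        logger.warning("optimal tracks contain %d gap frame-slots", n_gaps)
    return MttResult(assignment=assignment, objective=objective,
                     positions=positions)


def track_side_z(bottom_cols: np.ndarray,
                 side_candidates: list[FrameCandidates],
                 detector_width: int,
                 alpha: float = 0.1, v_base: float = 15.0,
                 box_displacement: np.ndarray | None = None,
                 tolerance_frac: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Most likely side-view (z) trajectory given a fixed bottom track.

    Side candidates incompatible with the bottom x at each frame (beyond the
    view-matching tolerance) are discarded, then the same MAP recursion runs
    as a single-object problem over the survivors.  Frames without a
    compatible candidate become gaps; their rows are linearly interpolated
    and flagged.

    Returns ``(side_rows, interpolated_mask)`` over frames; all-NaN rows if
    no side data exists at all.
    """
    n_frames = len(side_candidates)
    tol = tolerance_frac * detector_width
    filtered: list[FrameCandidates] = []
    for t in range(n_frames):
        f = side_candidates[t]
        if f.n_candidates and np.isfinite(bottom_cols[t]):
            ok = np.abs(f.positions[:, 0] - bottom_cols[t]) <= tol
        else:
            ok = np.zeros(f.n_candidates, dtype=bool)
        filtered.append(FrameCandidates(f.positions[ok], f.scores[:1, ok]))

    if all(f.n_candidates == 0 for f in filtered):
        logger.warning("no compatible side-view candidates: z track is empty")
        return np.full(n_frames, np.nan), np.ones(n_frames, dtype=bool)

    graph = CandidateGraph(frames=filtered, alpha=alpha, v_base=v_base,
                           box_displacement=box_displacement)
    res = track_mtt(graph, n_objects=1)
    rows = res.positions[0, :, 1]
    gap = ~np.isfinite(rows)
    if gap.any() and (~gap).any():
        idx = np.arange(n_frames, dtype=float)
        rows = rows.copy()
        rows[gap] = np.interp(idx[gap], idx[~gap], rows[~gap])
    return rows, gap


def brute_force_mtt(graph: CandidateGraph, n_objects: int) -> tuple[np.ndarray, float]:
    """Exhaustive search over all joint tracks (testing oracle; exponential).

    Enumerates every sequence of injective partial assignments and scores it
    directly from the objective; independent of the dynamic program.
    """
    frames = graph.frames
    per_frame_states = []
    for f in frames:
        scores = f.scores if f.scores.shape[0] == n_objects else \
            np.repeat(f.scores, n_objects, axis=0)
        sts = [tuple(s) for s in _enumerate_states(n_objects, f.n_candidates)]
        per_frame_states.append((sts, f.positions, scores))

    best_val = -np.inf
    best_path: list[tuple[int, ...]] | None = None

    def unary(t: int, state: tuple[int, ...]) -> float:
        _, _, scores = per_frame_states[t]
        return sum(scores[o, c] for o, c in enumerate(state) if c >= 0)

    def pair(t: int, a: tuple[int, ...], b: tuple[int, ...]) -> float:
        pa = per_frame_states[t][1]
        pb = per_frame_states[t + 1][1]
        total = 0.0
        for o in range(n_objects):
            ca, cb = a[o], b[o]
            if ca < 0 or cb < 0:
                continue
            d = float(np.linalg.norm(pa[ca] - pb[cb]))
            if d > graph.v_limit(t):
                return -np.inf
            total += graph.alpha * inverse_distance_score(d)
        return total

    def rec(t: int, path: list[tuple[int, ...]], value: float) -> None:
        nonlocal best_val, best_path
        if t == len(frames):
            if value > best_val:
                best_val = value
                best_path = list(path)
            return
        for state in per_frame_states[t][0]:
            v = value + unary(t, state)
            if t > 0:
                tv = pair(t - 1, path[-1], state)
                if tv == -np.inf:
                    continue
                v += tv
            path.append(state)
            rec(t + 1, path, v)
            path.pop()

    rec(0, [], 0.0)
    assert best_path is not None
    assignment = np.array(best_path, dtype=np.int64).T
    return assignment, float(best_val)
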