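"""Interlimb and whole-body coordination metrics.

All phases live on the circle [0, 1), expressed as fractions of the
reference paw's stride cycle.  Support patterns classify how many paws are
on the ground at each instant of the stride (splitting two-paw support into
diagonal vs other); double support between contralateral partners is signed,
negative when the partner lifts off before the reference touchdown (aerial
overlap at running speeds, searched back to 25% of the cycle).  Periodic
body features (tail segments, nose) get their phase relative to the hind-paw
alternation by circular cross-correlation, and a fixed time delay shows up
as a phase that grows linearly with cadence (time-locked), in contrast to a
constant phase offset (phase-locked).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

SUPPORT_CATEGORIES = ("four", "three", "two_diagonal", "two_other", "one", "zero")
DIAGONAL_PAIRS = ({"FR", "HL"}, {"FL", "HR"})


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction of phases on [0, 1) (mean resultant vector)."""
    ang = 2 * np.pi * np.asarray(phases, dtype=float)
    m = np.angle(np.mean(np.exp(1j * ang))) / (2 * np.pi)
    return float(m % 1.0)


def circular_resultant(phases: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]; 1 = perfectly concentrated."""
    ang = 2 * np.pi * np.asarray(phases, dtype=float)
    return float(np.abs(np.mean(np.exp(1j * ang))))


def stance_phase(ref_onset: float, stride_duration: float,
                 other_onsets: np.ndarray) -> float:
    """Touchdown timing of another limb as a fraction of the reference cycle.

    ``((t_other - t_ref) mod stride_duration) / stride_duration`` for the
    other paw's touchdown falling (cyclically) within the reference stride;
    NaN when the other paw never touches down in the window.
    """
    other = np.asarray(other_onsets, dtype=float)
    if other.size == 0:
        return np.nan
    rel = (other - ref_onset) % stride_duration
    in_window = (other >= ref_onset - stride_duration) & \
                (other < ref_onset + stride_duration)
    if not in_window.any():
        return np.nan
    # the touchdown closest (cyclically) to the reference onset
    candidates = rel[in_window]
    dist = np.minimum(candidates, stride_duration - candidates)
    return float(candidates[np.argmin(dist)] / stride_duration)


def _pair_category(down: frozenset) -> str:
    return "two_diagonal" if set(down) in DIAGONAL_PAIRS else "two_other"


def support_fractions(stance_intervals: dict[str, list[tuple[float, float]]],
                      ref_start: float, ref_end: float,
                      n_samples: int = 1000) -> dict[str, float]:
    """Fraction of the reference stride spent in each support category.

    ``stance_intervals`` maps each of the four paws to its stance intervals
    ``(touchdown, liftoff)`` in seconds; the reference stride is
    ``[ref_start, ref_end)``.  Categories: four, three, two_diagonal,
    two_other (homolateral + homologous pooled), one, zero.  Computed by
    dense sampling of the stride (interval arithmetic on the event grid
    would be equivalent; sampling keeps the code one line per category).
    """
    missing = {p for p in ("FR", "FL", "HR", "HL") if p not in stance_intervals}
    if missing:
        raise ValueError(f"missing stance intervals for paws: {sorted(missing)}")
    t = ref_start + (ref_end - ref_start) * (np.arange(n_samples) + 0.5) / n_samples
    down = {}
    for paw, ivals in stance_intervals.items():
        on = np.zeros(n_samples, dtype=bool)
        for a, b in ivals:
            on |= (t >= a) & (t < b)
        down[paw] = on
    counts = sum(down[p].astype(int) for p in ("FR", "FL", "HR", "HL"))
    fractions = {c: 0.0 for c in SUPPORT_CATEGORIES}
    fractions["four"] = float(np.mean(counts == 4))
    fractions["three"] = float(np.mean(counts == 3))
    fractions["one"] = float(np.mean(counts == 1))
    fractions["zero"] = float(np.mean(counts == 0))
    two = counts == 2
    if two.any():
        diag = np.zeros(n_samples, dtype=bool)
        for pair in DIAGONAL_PAIRS:
            a, b = sorted(pair)
            diag |= down[a] & down[b]
        fractions["two_diagonal"] = float(np.mean(two & diag))
        fractions["two_other"] = float(np.mean(two & ~diag))
    return fractions


def double_support(ref_touchdown: float, stride_duration: float,
                   contra_liftoffs: np.ndarray,
                   back_window: float = 0.25) -> float:
    """Signed double support, percent of the reference stride cycle.

    Time from the reference paw's touchdown to the contralateral paw's
    lift-off, as a percentage of stride duration: positive when the partner
    lifts off after the touchdown, negative when before (searched backwards
    up to ``back_window`` of the cycle).  NaN when no lift-off falls in
    ``[-back_window, 1) * stride_duration`` around the touchdown.
    """
    lifts = np.asarray(contra_liftoffs, dtype=float)
    if lifts.size == 0:
        return np.nan
    rel = (lifts - ref_touchdown) / stride_duration
    ok = (rel >= -back_window) & (rel < 1.0)
    if not ok.any():
        return np.nan
    # the lift-off nearest the touchdown defines the support overlap
    best = rel[ok][np.argmin(np.abs(rel[ok]))]
    return float(best * 100.0)


def paw_distance(front_liftoff_xy: tuple[float, float],
                 hind_touchdown_xy: tuple[float, float]) -> float:
    """Horizontal-plane distance (mm) from a front paw's lift-off position to
    the ipsilateral hind paw's touchdown position on the subsequent stride."""
    fx, fy = front_liftoff_xy
    hx, hy = hind_touchdown_xy
    if not (np.isfinite(fx) and np.isfinite(fy) and np.isfinite(hx)
            and np.isfinite(hy)):
        return np.nan
    return float(np.hypot(hx - fx, hy - fy))


def feature_phase(feature: np.ndarray, reference: np.ndarray) -> float:
    """Phase of a periodic feature relative to the hind-paw difference signal.

    Both signals are normalized to one stride (same length); the phase is
    the circular lag in [0, 1) maximizing their cross-correlation.  The
    reference is conventionally ``x_HR - x_HL`` resampled to the stride.
    NaN for constant signals.
    """
    f = np.asarray(feature, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape or f.ndim != 1:
        raise ValueError("feature and reference must be 1D of equal length")
    f = f - f.mean()
    r = r - r.mean()
    if not f.any() or not r.any():
        logger.warning("constant signal: feature phase undefined")
        return np.nan
    n = len(f)
    # circular cross-correlation via FFT: corr[k] = sum_t r[t] f[t+k]
    corr = np.fft.irfft(np.conj(np.fft.rfft(r)) * np.fft.rfft(f), n)
    lag = int(np.argmax(corr))
    # feature delayed by d samples relative to reference peaks at k = d
    return float(lag / n)


def unwrap_phases(phases: np.ndarray) -> np.ndarray:
    """Unwrap phases in cycles across ascending bins, assuming the true
    change between adjacent bins is below half a cycle."""
    p = np.asarray(phases, dtype=float).copy()
    for i in range(1, len(p)):
        step = p[i] - p[i - 1]
        p[i] -= np.round(step)
    return p


def phase_vs_cadence_delay(cadences: np.ndarray, phases: np.ndarray
                           ) -> dict[str, float]:
    """Fit a fixed time delay from phases measured across speed bins.

    A feature lagging the stride by a constant time delay D has phase
    ``cadence * D (mod 1)``; regressing unwrapped phase on cadence therefore
    estimates D as the slope (in seconds).  Requires at least 3 bins.

    Returns dict with ``delay_s``, ``intercept``, ``r_squared`` and the
    unwrapped phases used.
    """
    cad = np.asarray(cadences, dtype=float)
    ph = np.asarray(phases, dtype=float)
    if cad.size < 3:
        raise ValueError("delay regression needs phases from >= 3 speed bins")
    order = np.argsort(cad)
    cad, ph = cad[order], ph[order]
    unwrapped = unwrap_phases(ph)
    if np.any(np.abs(np.diff(unwrapped)) >= 0.5):
        logger.warning("phase unwrapping ambiguous: adjacent bins differ by >= 0.5 cycle")
    design = np.column_stack([cad, np.ones_like(cad)])
    coef, *_ = np.linalg.lstsq(design, unwrapped, rcond=None)
    pred = design @ coef
    ss_res = float(np.sum((unwrapped - pred) ** 2))
    ss_tot = float(np.sum((unwrapped - unwrapped.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"delay_s": float(coef[0]), "intercept": float(coef[1]),
            "r_squared": r2, "unwrapped_phases": unwrapped,
            "cadences": cad}


def correlation_matrix(trajectories: dict[str, np.ndarray]
                       ) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations between average z trajectories normalized to
    100% of the reference (FR) stride cycle.

    All trajectories must share their length; zero-variance entries give
    NaN rows/columns (flagged with a warning).  Returns (matrix, names).
    """
    names = list(trajectories)
    arrs = [np.asarray(trajectories[k], dtype=float) for k in names]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("all trajectories must be 1D of equal length")
    mat = np.full((len(names), len(names)), np.nan)
    stds = [a.std() for a in arrs]
    for i in range(len(names)):
        mat[i, i] = 1.0
        for j in range(i + 1, len(names)):
            if stds[i] == 0 or stds[j] == 0:
                continue
            r = np.corrcoef(arrs[i], arrs[j])[0, 1]
            mat[i, j] = mat[j, i] = r
    if any(s == 0 for s in stds):
        logger.warning("zero-variance trajectory: undefined correlation entries")
    return mat, names


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample standard deviation over the mean (ddof=1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(sd / mean)
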