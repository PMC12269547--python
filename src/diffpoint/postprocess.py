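"""Prediction smoothing and penalized changepoint detection.

Predicted alpha(t) and log10(K+1)(t) series are noisy; before changepoint
detection they are smoothed by (i) replacing maximal runs whose range is
at most 0.01 with their mean and (ii) a centred window-3 median filter.
Predicted state series instead obey a minimum dwell of three frames: any
shorter state segment is invalid and takes its predecessor's value.

Changepoints in the smoothed continuous series are found with PELT
(Pruned Exact Linear Time) under a least-squares (L2) segment cost and a
per-changepoint penalty of 0.3, with segments of at least three frames.
Series are min-max normalised first so one penalty serves both alpha and
K.  State changepoints are simply the label changes.  Finally the per-
variable changepoint sets are merged around the K-derived anchors,
deduplicating points closer than five frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmoothingParams",
    "SegmentationParams",
    "merge_plateaus",
    "median_filter",
    "enforce_min_state_duration",
    "minmax_normalise",
    "pelt_segment",
    "state_changepoints",
    "merge_changepoint_sets",
    "smooth_continuous",
    "detect_changepoints",
]


@dataclass
class SmoothingParams:
    plateau_tol: float = 0.01
    median_window: int = 3
    min_state_duration: int = 3

    def __post_init__(self) -> None:
        if self.plateau_tol < 0:
            raise ValueError("plateau tolerance must be >= 0")
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise ValueError("median window must be odd and positive")
        if self.min_state_duration < 1:
            raise ValueError("minimum state duration must be >= 1")


@dataclass
class SegmentationParams:
    penalty: float = 0.3
    min_size: int = 3
    dedup_window: int = 5

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


def merge_plateaus(series: np.ndarray, tol: float = 0.01) -> np.ndarray:
    """Replace greedy left-to-right maximal runs with range <= tol by their mean."""
    v = np.asarray(series, dtype=float)
    out = v.copy()
    i = 0
    n = v.size
    while i < n:
        lo = hi = v[i]
        j = i + 1
        while j < n:
            lo2, hi2 = min(lo, v[j]), max(hi, v[j])
            if hi2 - lo2 > tol:
                break
            lo, hi = lo2, hi2
            j += 1
        out[i:j] = v[i:j].mean()
        i = j
    return out


def median_filter(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred sliding median; endpoints use shrunken windows."""
    v = np.asarray(series, dtype=float)
    half = window // 2
    n = v.size
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(v[max(0, i - half) : min(n, i + half + 1)])
    return out


def enforce_min_state_duration(states: np.ndarray, min_duration: int = 3) -> np.ndarray:
    """Absorb state segments shorter than ``min_duration`` into the
    preceding state (a short leading segment takes the following state's
    value); repeated until no short segment remains."""
    s = np.asarray(states).copy()
    while True:
        cps = np.flatnonzero(np.diff(s)) + 1
        bounds = np.concatenate([[0], cps, [s.size]])
        lengths = np.diff(bounds)
        short = np.flatnonzero(lengths < min_duration)
        if short.size == 0 or lengths.size == 1:
            return s
        i = short[0]
        a, b = bounds[i], bounds[i + 1]
        s[a:b] = s[b] if i == 0 else s[a - 1]


def minmax_normalise(series: np.ndarray) -> np.ndarray:
    """Map to [0, 1]; a constant series maps to zeros (nothing to detect)."""
    v = np.asarray(series, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _l2_cost_fns(v: np.ndarray):
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def cost(a: int, b: int) -> float:
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / (b - a)

    return cost


def pelt_segment(
    series: np.ndarray,
    params: SegmentationParams | None = None,
    normalise: bool = True,
) -> np.ndarray:
    """Exact penalized L2 segmentation of one series.

    Minimises sum of within-segment squared deviations plus
    ``penalty`` per changepoint, every segment at least ``min_size``
    frames.  PELT pruning keeps the optimum exact for this cost (it
    is subadditive).  Series shorter than ``2 * min_size`` cannot hold
    a changepoint and return the empty set.
    """
    p = params or SegmentationParams()
    v = np.asarray(series, dtype=float)
    n = v.size
    if n < 2 * p.min_size:
        return np.array([], dtype=int)
    if normalise:
        v = minmax_normalise(v)
    cost = _l2_cost_fns(v)
    F = np.full(n + 1, np.inf)
    F[0] = -p.penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    removal_time: dict[int, int] = {}
    for t in range(p.min_size, n + 1):
        candidates = [s for s in candidates if removal_time.get(s, n + 1) > t]
        admissible = [s for s in candidates if t - s >= p.min_size]
        vals = [F[s] + cost(s, t) + p.penalty for s in admissible]
        j = int(np.argmin(vals))
        F[t] = vals[j]
        last[t] = admissible[j]
        # PELT pruning: once F[s] + cost(s, t) exceeds F[t], candidate s is
        # dominated by t itself -- but only at horizons where t is already
        # admissible, so removal activates min_size frames later
        for s in admissible:
            if F[s] + cost(s, t) > F[t] and s not in removal_time:
                removal_time[s] = t + p.min_size
        candidates.append(t - p.min_size + 1)
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return np.array(sorted(cps), dtype=int)


def state_changepoints(states: np.ndarray) -> np.ndarray:
    """Frames at which the (smoothed) state label changes."""
    s = np.asarray(states)
    return np.flatnonzero(np.diff(s) != 0) + 1


def merge_changepoint_sets(
    anchor: np.ndarray,
    others: list[np.ndarray],
    window: int = 5,
) -> np.ndarray:
    """Merge changepoint sets around the anchor (K-derived) points.

    Anchor points are kept verbatim; candidates from the other sets are
    added in ascending order only when no already-retained point lies
    strictly within ``window`` frames.
    """
    retained = sorted(int(c) for c in np.asarray(anchor, dtype=int))
    candidates = sorted(
        int(c) for arr in others for c in np.asarray(arr, dtype=int)
    )
    for c in candidates:
        if all(abs(c - r) >= window for r in retained):
            retained.append(c)
            retained.sort()
    return np.array(retained, dtype=int)


def smooth_continuous(series: np.ndarray, params: SmoothingParams | None = None) -> np.ndarray:
    """Plateau merge followed by the median filter (alpha / log-K series)."""
    p = params or SmoothingParams()
    return median_filter(merge_plateaus(series, p.plateau_tol), p.median_window)


def detect_changepoints(
    alpha_hat: np.ndarray | None = None,
    logK_hat: np.ndarray | None = None,
    state_hat: np.ndarray | None = None,
    smoothing: SmoothingParams | None = None,
    segmentation: SegmentationParams | None = None,
    variables: tuple[str, ...] = ("alpha", "K"),
) -> dict[str, np.ndarray]:
    """Full changepoint pipeline for one trajectory's predicted series.

    Returns per-variable changepoint sets plus the merged set under key
    ``"merged"``.  The merge anchors on K when it participates (the best-
    behaved series); the default variable subset is alpha + K.
    """
    sp = smoothing or SmoothingParams()
    sg = segmentation or SegmentationParams()
    sets: dict[str, np.ndarray] = {}
    if alpha_hat is not None:
        sets["alpha"] = pelt_segment(smooth_continuous(alpha_hat, sp), sg)
    if logK_hat is not None:
        sets["K"] = pelt_segment(smooth_continuous(logK_hat, sp), sg)
    if state_hat is not None:
        sets["state"] = state_changepoints(
            enforce_min_state_duration(state_hat, sp.min_state_duration)
        )
    use = [v for v in variables if v in sets]
    if not use:
        sets["merged"] = np.array([], dtype=int)
        return sets
    if "K" in use:
        anchor = sets["K"]
        others = [sets[v] for v in use if v != "K"]
    else:
        anchor = sets[use[0]]
        others = [sets[v] for v in use[1:]]
    sets["merged"] = merge_changepoint_sets(anchor, others, sg.dedup_window)
    return sets
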