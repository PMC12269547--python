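"""Trajectory simulation for heterogeneous anomalous diffusion.

Five biological scenarios are modelled, all built on piecewise fractional
Brownian motion in a square field of view (FOV):

* **SSM** (single state): one (alpha, K) pair for the whole trajectory.
* **MSM** (multi state): a Markov chain over 2-3 diffusive states; at each
  transition the new state's (alpha_i, K_i) applies.
* **QTM** (quenched trap): immobilising traps scattered in the FOV; a
  trapped particle is frozen with alpha = K = 0 and state 0 until it
  escapes (geometric dwell, per-frame unbinding probability).
* **TCM** (transient confinement): non-overlapping circular compartments;
  inside one, confined (alpha, K) applies with state 1 and the wall
  reflects outgoing steps unless a per-crossing transition probability
  lets the particle through.
* **DIM** (dimerisation): two particles that bind on contact and then
  co-diffuse with shared displacements and dimer (alpha, K) until a
  per-frame unbinding event.

Per-frame labels are the anomalous exponent alpha(t), generalised
diffusion coefficient K(t) (pixels^2 / frame^alpha) and discrete state
s(t) in {0 immobile, 1 confined, 2 free, 3 directed}.  The state is
derived from the physical situation: s=0 iff trapped (alpha=K=0), s=1 iff
inside a compartment, otherwise s=3 when alpha >= 1.9 and s=2 below.

Each label segment lasts at least ``MIN_SEGMENT`` frames; shorter runs are
merged into their predecessor (the leading run takes its successor's
values).  fGN memory is reset at every changepoint: segments are drawn
independently and appended at the current position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fgn import sample_fgn

__all__ = [
    "MIN_SEGMENT",
    "MODEL_KINDS",
    "SimConfig",
    "Trajectory",
    "LabelSeries",
    "sample_K",
    "state_for",
    "simulate_segment",
    "markov_state_sequence",
    "simulate_ssm",
    "simulate_msm",
    "simulate_qtm",
    "simulate_tcm",
    "simulate_dim",
    "simulate",
    "simulate_two_segment",
    "build_dataset",
]

MIN_SEGMENT = 3
MODEL_KINDS = ("SSM", "MSM", "QTM", "TCM", "DIM")
T_MIN, T_MAX = 20, 200
DIRECTED_ALPHA = 1.9


# ---------------------------------------------------------------------------
# containers


@dataclass
class Trajectory:
    """2-D pixel coordinates of one particle over 20-200 frames."""

    traj_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class LabelSeries:
    """Per-frame ground truth: alpha(t), K(t), s(t) and true changepoints.

    A changepoint at frame c separates segments [0, c) and [c, T)
    (half-open, 0-based).  Consecutive changepoints are >= 3 frames apart
    and at least one of alpha, K, s differs across each one.
    """

    alpha: np.ndarray
    K: np.ndarray
    state: np.ndarray
    changepoints: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.state = np.asarray(self.state, dtype=int)
        self.changepoints = np.asarray(self.changepoints, dtype=int)

    def __len__(self) -> int:
        return self.alpha.size


@dataclass
class SimConfig:
    """Sampling configuration for one simulated trajectory.

    Fields left as ``None`` are drawn from their standard ranges:
    MSM: 2-3 states, dwell-dominant transition matrix; QTM: unbinding
    probability U[0, 0.1], trap radius U[0.5, 2] px, 100-300 traps;
    DIM: unbinding probability U[0, 0.1], interaction radius U[0.5, 5] px;
    TCM: transition probability U[0, 0.3], 30-50 compartments of radius
    U[5, 10] px.  K is sampled log-uniformly (uniform in log10(K+1)).
    """

    model_kind: str
    T: int | None = None
    T_range: tuple[int, int] | None = None
    fov: float = 128.0
    alpha_range: tuple[float, float] = (0.0, 2.0)
    K_range: tuple[float, float] = (1e-12, 1e6)
    # MSM
    n_states: int | None = None
    transition_matrix: np.ndarray | None = None
    # QTM / DIM shared
    unbinding_prob: float | None = None
    # QTM
    trap_radius: float | None = None
    n_traps: int | None = None
    # DIM
    interaction_radius: float | None = None
    # TCM
    transition_prob: float | None = None
    n_compartments: int | None = None
    compartment_radius: float | None = None
    # dataset variants
    alpha_only_change: bool = False
    k_only_change: bool = False
    # optional overrides (mostly for targeted tests)
    start: tuple[float, float] | Sequence[tuple[float, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        lo, hi = self.alpha_range
        if not (0.0 <= lo <= hi <= 2.0):
            raise ValueError("alpha_range must lie within [0, 2]")
        lo, hi = self.K_range
        if not (1e-12 <= lo <= hi <= 1e6):
            raise ValueError("K_range must lie within [1e-12, 1e6]")
        if self.T is not None and not (T_MIN <= self.T <= T_MAX):
            raise ValueError(f"T must lie in [{T_MIN}, {T_MAX}]")
        if self.T_range is not None:
            lo, hi = self.T_range
            if not (T_MIN <= lo <= hi <= T_MAX):
                raise ValueError(f"T_range must lie within [{T_MIN}, {T_MAX}]")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            if P.ndim != 2 or P.shape[0] != P.shape[1]:
                raise ValueError("transition matrix must be square")
            if (P < 0).any() or (P > 1).any() or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must be stochastic")
            self.transition_matrix = P
        for p in (self.unbinding_prob, self.transition_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.alpha_only_change and self.k_only_change:
            raise ValueError("at most one of alpha_only_change / k_only_change")


# ---------------------------------------------------------------------------
# primitive sampling


def sample_K(rng: np.random.Generator, K_range: tuple[float, float]) -> float:
    """Draw K log-uniformly: uniform in log10(K+1) over the range.

    The admissible range spans 18 decades; uniform sampling would almost
    never produce small diffusivities.
    """
    lo, hi = np.log10(K_range[0] + 1.0), np.log10(K_range[1] + 1.0)
    return float(10.0 ** rng.uniform(lo, hi) - 1.0)


def _sample_alpha(rng: np.random.Generator, alpha_range) -> float:
    return float(rng.uniform(*alpha_range))


def state_for(alpha: float, K: float, *, trapped: bool = False, confined: bool = False) -> int:
    """Map a physical situation onto the 4-state taxonomy."""
    if trapped or (alpha == 0.0 and K == 0.0):
        return 0
    if confined:
        return 1
    return 3 if alpha >= DIRECTED_ALPHA else 2


def simulate_segment(
    alpha: float, K: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """``n`` fBM displacements with per-axis MSD 2*K*t^alpha (2-D: 4*K*t^alpha)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if K == 0.0:
        return np.zeros(n), np.zeros(n)
    scale = np.sqrt(2.0 * K)
    return scale * sample_fgn(alpha, n, rng), scale * sample_fgn(alpha, n, rng)


class _Stepper:
    """Serves displacements for the current regime; redrawn at changepoints."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._dx = self._dy = None
        self._i = 0

    def reset(self, alpha: float, K: float, n_max: int) -> None:
        self._dx, self._dy = simulate_segment(alpha, K, max(n_max, 1), self.rng)
        self._i = 0

    def step(self) -> tuple[float, float]:
        dx, dy = self._dx[self._i], self._dy[self._i]
        self._i += 1
        return dx, dy


# ---------------------------------------------------------------------------
# label post-processing


def _segment_bounds(alpha: np.ndarray, K: np.ndarray, state: np.ndarray) -> np.ndarray:
    change = (np.diff(alpha) != 0) | (np.diff(K) != 0) | (np.diff(state) != 0)
    return np.flatnonzero(change) + 1


def finalize_labels(alpha: np.ndarray, K: np.ndarray, state: np.ndarray) -> LabelSeries:
    """Merge label runs shorter than ``MIN_SEGMENT`` and emit changepoints.

    Short runs take the predecessor's values; a short leading run takes the
    following run's values.  Iterates to a fixed point, so the result never
    contains a segment under 3 frames.
    """
    alpha = np.array(alpha, dtype=float)
    K = np.array(K, dtype=float)
    state = np.array(state, dtype=int)
    while True:
        cps = _segment_bounds(alpha, K, state)
        bounds = np.concatenate([[0], cps, [alpha.size]])
        lengths = np.diff(bounds)
        short = np.flatnonzero(lengths < MIN_SEGMENT)
        if short.size == 0 or lengths.size == 1:
            break
        i = short[0]
        a, b = bounds[i], bounds[i + 1]
        src = b if i == 0 else a - 1  # successor's first frame / predecessor's last
        alpha[a:b] = alpha[src]
        K[a:b] = K[src]
        state[a:b] = state[src]
    return LabelSeries(alpha, K, state, _segment_bounds(alpha, K, state))


def _first_exit(x: np.ndarray, y: np.ndarray, fov: float) -> int:
    """Number of leading frames inside the [0, fov]^2 field of view."""
    outside = (x < 0) | (x > fov) | (y < 0) | (y > fov)
    hits = np.flatnonzero(outside)
    return int(hits[0]) if hits.size else x.size


# ---------------------------------------------------------------------------
# model simulators


def _rng_for(cfg: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(cfg.seed)


def _draw_T(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.T is not None:
        return cfg.T
    lo, hi = cfg.T_range if cfg.T_range is not None else (T_MIN, T_MAX)
    return int(rng.integers(lo, hi + 1))


def _start(cfg: SimConfig, rng: np.random.Generator, which: int = 0) -> tuple[float, float]:
    if cfg.start is not None:
        s = np.asarray(cfg.start, dtype=float)
        if s.ndim == 1:
            return float(s[0]), float(s[1])
        return float(s[which, 0]), float(s[which, 1])
    return float(rng.uniform(0, cfg.fov)), float(rng.uniform(0, cfg.fov))


_MAX_PLACEMENT_TRIES = 50
_MAX_PARAM_TRIES = 200


def _with_fov_retries(cfg, rng, build):
    """Run ``build`` until the FOV-truncated trajectory keeps >= 20 frames.

    ``build(rng)`` returns (x, y, alpha, K, state) for the full horizon.
    Retries first re-place the particle; after many failures fresh
    parameters are drawn inside ``build`` itself via its rng, mirroring the
    survival bias of the field of view (fast particles escape and are
    discarded, which in practice caps usable K near 10^3 px^2/frame).
    """
    for _ in range(_MAX_PARAM_TRIES):
        x, y, alpha, K, state = build(rng)
        keep = _first_exit(x, y, cfg.fov)
        if keep >= T_MIN:
            labels = finalize_labels(alpha[:keep], K[:keep], state[:keep])
            return x[:keep], y[:keep], labels
    raise RuntimeError("could not place a trajectory inside the field of view")


def simulate_ssm(cfg: SimConfig, rng: np.random.Generator | None = None):
    """One (alpha, K) pair throughout; no changepoints."""
    rng = _rng_for(cfg, rng)
    T = _draw_T(cfg, rng)

    def build(rng):
        alpha = _sample_alpha(rng, cfg.alpha_range)
        K = sample_K(rng, cfg.K_range)
        for _ in range(_MAX_PLACEMENT_TRIES):
            x0, y0 = _start(cfg, rng)
            dx, dy = simulate_segment(alpha, K, T - 1, rng)
            x = x0 + np.concatenate([[0.0], np.cumsum(dx)])
            y = y0 + np.concatenate([[0.0], np.cumsum(dy)])
            if _first_exit(x, y, cfg.fov) >= T_MIN:
                break
        s = state_for(alpha, K)
        return x, y, np.full(T, alpha), np.full(T, K), np.full(T, s)

    x, y, labels = _with_fov_retries(cfg, rng, build)
    return Trajectory("ssm-0", x, y), labels


def _dwell_dominant_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Row-stochastic matrix with stay probability U[0.9, 0.99] per state."""
    P = np.zeros((n, n))
    for i in range(n):
        stay = rng.uniform(0.9, 0.99)
        P[i, i] = stay
        off = rng.uniform(0.1, 1.0, n - 1)
        off = off / off.sum() * (1.0 - stay)
        P[i, [j for j in range(n) if j != i]] = off
    return P


def markov_state_sequence(P: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Raw Markov chain over state indices (before min-dwell enforcement)."""
    n = P.shape[0]
    seq = np.empty(T, dtype=int)
    seq[0] = rng.integers(n)
    for t in range(1, T):
        seq[t] = rng.choice(n, p=P[seq[t - 1]])
    return seq


def _state_params(cfg: SimConfig, n: int, rng: np.random.Generator):
    """Per-state (alpha_i, K_i); single-variable-change variants pin the other."""
    alphas = np.array([_sample_alpha(rng, cfg.alpha_range) for _ in range(n)])
    Ks = np.array([sample_K(rng, cfg.K_range) for _ in range(n)])
    if cfg.alpha_only_change:
        Ks[:] = Ks[0]
    if cfg.k_only_change:
        alphas[:] = alphas[0]
    return alphas, Ks


def simulate_msm(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Markov switching between 2-3 free-diffusion states."""
    rng = _rng_for(cfg, rng)
    T = _draw_T(cfg, rng)

    def build(rng):
        if cfg.transition_matrix is not None:
            P = cfg.transition_matrix
        else:
            n = cfg.n_states if cfg.n_states is not None else int(rng.integers(2, 4))
            P = _dwell_dominant_matrix(n, rng)
        n = P.shape[0]
        alphas, Ks = _state_params(cfg, n, rng)
        seq = markov_state_sequence(P, T, rng)
        alpha_t = alphas[seq]
        K_t = Ks[seq]
        state_t = np.array([state_for(alphas[i], Ks[i]) for i in seq])
        # piecewise fBM: an independent draw per dwell run
        x = np.empty(T)
        y = np.empty(T)
        x[0], y[0] = _start(cfg, rng)
        bounds = np.concatenate([[0], _segment_bounds(alpha_t, K_t, state_t), [T]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            lo = max(a, 1)  # frame 0 has no incoming displacement
            if b <= lo:
                continue
            dx, dy = simulate_segment(alpha_t[lo], K_t[lo], b - lo, rng)
            x[lo:b] = x[lo - 1] + np.cumsum(dx)
            y[lo:b] = y[lo - 1] + np.cumsum(dy)
        return x, y, alpha_t, K_t, state_t

    x, y, labels = _with_fov_retries(cfg, rng, build)
    return Trajectory("msm-0", x, y), labels


def simulate_qtm(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Quenched traps: binding on contact, frozen until geometric escape."""
    rng = _rng_for(cfg, rng)
    T = _draw_T(cfg, rng)
    p_u = cfg.unbinding_prob if cfg.unbinding_prob is not None else float(rng.uniform(0, 0.1))
    r_trap = cfg.trap_radius if cfg.trap_radius is not None else float(rng.uniform(0.5, 2.0))
    n_traps = cfg.n_traps if cfg.n_traps is not None else int(rng.integers(100, 301))
    traps = rng.uniform(0, cfg.fov, size=(n_traps, 2)) if n_traps else np.empty((0, 2))

    def in_trap(px, py, exclude=None):
        if traps.shape[0] == 0:
            return None
        d2 = (traps[:, 0] - px) ** 2 + (traps[:, 1] - py) ** 2
        if exclude is not None:
            d2[exclude] = np.inf
        j = int(np.argmin(d2))
        return j if d2[j] <= r_trap**2 else None

    def build(rng):
        alpha_f = _sample_alpha(rng, cfg.alpha_range)
        K_f = sample_K(rng, cfg.K_range)
        s_free = state_for(alpha_f, K_f)
        x = np.empty(T)
        y = np.empty(T)
        alpha_t = np.empty(T)
        K_t = np.empty(T)
        state_t = np.empty(T, dtype=int)
        x[0], y[0] = _start(cfg, rng)
        stepper = _Stepper(rng)
        stepper.reset(alpha_f, K_f, T - 1)
        trap_idx = in_trap(x[0], y[0])
        trapped = trap_idx is not None
        escaped_from = None

        def label(t, is_trapped):
            if is_trapped:
                alpha_t[t] = K_t[t] = 0.0
                state_t[t] = 0
            else:
                alpha_t[t], K_t[t], state_t[t] = alpha_f, K_f, s_free

        label(0, trapped)
        for t in range(1, T):
            if trapped:
                if rng.random() < p_u:
                    trapped = False
                    escaped_from = trap_idx
                    stepper.reset(alpha_f, K_f, T - t)  # memory reset on release
                    dx, dy = stepper.step()
                    x[t], y[t] = x[t - 1] + dx, y[t - 1] + dy
                else:
                    x[t], y[t] = x[t - 1], y[t - 1]
                label(t, trapped)
                continue
            dx, dy = stepper.step()
            x[t], y[t] = x[t - 1] + dx, y[t - 1] + dy
            if escaped_from is not None and in_trap(x[t], y[t]) != escaped_from:
                escaped_from = None
            hit = in_trap(x[t], y[t], exclude=escaped_from)
            if hit is not None:
                trapped, trap_idx = True, hit
            label(t, trapped)
        return x, y, alpha_t, K_t, state_t

    x, y, labels = _with_fov_retries(cfg, rng, build)
    return Trajectory("qtm-0", x, y), labels


def _place_compartments(
    n: int, radius: float, fov: float, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping disc centres by rejection; keeps what fits."""
    centres: list[np.ndarray] = []
    tries = 0
    while len(centres) < n and tries < 2000:
        c = rng.uniform(radius, fov - radius, 2)
        if all(np.hypot(*(c - o)) > 2 * radius for o in centres):
            centres.append(c)
        tries += 1
    return np.array(centres) if centres else np.empty((0, 2))


def simulate_tcm(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Transient confinement in reflecting circular compartments."""
    rng = _rng_for(cfg, rng)
    T = _draw_T(cfg, rng)
    p_t = cfg.transition_prob if cfg.transition_prob is not None else float(rng.uniform(0, 0.3))
    radius = (
        cfg.compartment_radius
        if cfg.compartment_radius is not None
        else float(rng.uniform(5.0, 10.0))
    )
    n_comp = cfg.n_compartments if cfg.n_compartments is not None else int(rng.integers(30, 51))
    comps = _place_compartments(n_comp, radius, cfg.fov, rng)

    def containing(px, py):
        if comps.shape[0] == 0:
            return None
        d2 = (comps[:, 0] - px) ** 2 + (comps[:, 1] - py) ** 2
        j = int(np.argmin(d2))
        return j if d2[j] <= radius**2 else None

    def build(rng):
        alpha_f = _sample_alpha(rng, cfg.alpha_range)
        K_f = sample_K(rng, cfg.K_range)
        # confined motion is never "directed": clamp below 1.9 even when the
        # trajectory-level alpha range (e.g. the directed-variant [1.9, 2])
        # sits above it
        conf_hi = min(cfg.alpha_range[1], DIRECTED_ALPHA - 1e-9)
        conf_lo = min(cfg.alpha_range[0], conf_hi)
        alpha_c = float(rng.uniform(conf_lo, conf_hi))
        K_c = sample_K(rng, cfg.K_range)
        if cfg.alpha_only_change:
            K_c = K_f
        if cfg.k_only_change:
            alpha_c = min(alpha_f, conf_hi)
        s_free = state_for(alpha_f, K_f)

        x = np.empty(T)
        y = np.empty(T)
        alpha_t = np.empty(T)
        K_t = np.empty(T)
        state_t = np.empty(T, dtype=int)
        x[0], y[0] = _start(cfg, rng)
        comp = containing(x[0], y[0])
        stepper = _Stepper(rng)

        def label(t, inside):
            if inside:
                alpha_t[t], K_t[t], state_t[t] = alpha_c, K_c, 1
            else:
                alpha_t[t], K_t[t], state_t[t] = alpha_f, K_f, s_free

        def reset_for(inside, remaining):
            if inside:
                stepper.reset(alpha_c, K_c, remaining)
            else:
                stepper.reset(alpha_f, K_f, remaining)

        reset_for(comp is not None, T - 1)
        label(0, comp is not None)
        for t in range(1, T):
            dx, dy = stepper.step()
            px, py = x[t - 1] + dx, y[t - 1] + dy
            if comp is not None:
                cx, cy = comps[comp]
                if (px - cx) ** 2 + (py - cy) ** 2 > radius**2:
                    if rng.random() < p_t:  # escape through the wall
                        comp = containing(px, py)
                        reset_for(comp is not None, T - t)
                    else:  # radial reflection back inside
                        d = np.hypot(px - cx, py - cy)
                        rr = np.clip(2 * radius - d, 0.0, radius)
                        px = cx + (px - cx) / d * rr
                        py = cy + (py - cy) / d * rr
            else:
                entered = containing(px, py)
                if entered is not None:
                    comp = entered
                    reset_for(True, T - t)
            x[t], y[t] = px, py
            label(t, comp is not None)
        return x, y, alpha_t, K_t, state_t

    x, y, labels = _with_fov_retries(cfg, rng, build)
    return Trajectory("tcm-0", x, y), labels


def simulate_dim(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Two particles that dimerise on contact and co-diffuse until unbinding.

    Returns a list of two (Trajectory, LabelSeries) pairs, one per particle
    (both are usable, labelled trajectories).
    """
    rng = _rng_for(cfg, rng)
    T = _draw_T(cfg, rng)
    p_u = cfg.unbinding_prob if cfg.unbinding_prob is not None else float(rng.uniform(0, 0.1))
    radius = (
        cfg.interaction_radius
        if cfg.interaction_radius is not None
        else float(rng.uniform(0.5, 5.0))
    )

    for _ in range(_MAX_PARAM_TRIES):
        free = [
            (_sample_alpha(rng, cfg.alpha_range), sample_K(rng, cfg.K_range)) for _ in range(2)
        ]
        alpha_d = _sample_alpha(rng, cfg.alpha_range)
        K_d = sample_K(rng, cfg.K_range)
        if cfg.alpha_only_change:
            K_d = free[0][1]
            free = [(free[0][0], K_d), (free[1][0], K_d)]
        if cfg.k_only_change:
            alpha_d = free[0][0]
            free = [(alpha_d, free[0][1]), (alpha_d, free[1][1])]

        x = np.empty((2, T))
        y = np.empty((2, T))
        alpha_t = np.empty((2, T))
        K_t = np.empty((2, T))
        state_t = np.empty((2, T), dtype=int)
        for i in range(2):
            x[i, 0], y[i, 0] = _start(cfg, rng, which=i)
        steppers = [_Stepper(rng), _Stepper(rng)]
        for i in range(2):
            steppers[i].reset(*free[i], T - 1)
        dimer_stepper = _Stepper(rng)

        def sep(t):
            return np.hypot(x[0, t] - x[1, t], y[0, t] - y[1, t])

        bound = sep(0) <= radius
        sep_required = False  # must separate past the radius before rebinding
        if bound:
            dimer_stepper.reset(alpha_d, K_d, T - 1)

        def label(t):
            for i in range(2):
                a, K = (alpha_d, K_d) if bound else free[i]
                alpha_t[i, t], K_t[i, t] = a, K
                state_t[i, t] = state_for(a, K)

        label(0)
        for t in range(1, T):
            if bound:
                dx, dy = dimer_stepper.step()
                for i in range(2):
                    x[i, t], y[i, t] = x[i, t - 1] + dx, y[i, t - 1] + dy
                if rng.random() < p_u:
                    bound = False
                    sep_required = True
                    for i in range(2):
                        steppers[i].reset(*free[i], T - t)
            else:
                for i in range(2):
                    dx, dy = steppers[i].step()
                    x[i, t], y[i, t] = x[i, t - 1] + dx, y[i, t - 1] + dy
                if sep_required and sep(t) > radius:
                    sep_required = False
                if not sep_required and sep(t) <= radius:
                    bound = True
                    dimer_stepper.reset(alpha_d, K_d, T - t)
            label(t)

        results = []
        for i in range(2):
            keep = _first_exit(x[i], y[i], cfg.fov)
            if keep < T_MIN:
                results = None
                break
            labels = finalize_labels(alpha_t[i, :keep], K_t[i, :keep], state_t[i, :keep])
            results.append((Trajectory(f"dim-{i}", x[i, :keep], y[i, :keep]), labels))
        if results is not None:
            return results
    raise RuntimeError("could not place a dimer pair inside the field of view")


_SIMULATORS = {
    "SSM": simulate_ssm,
    "MSM": simulate_msm,
    "QTM": simulate_qtm,
    "TCM": simulate_tcm,
    "DIM": simulate_dim,
}


def simulate(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Dispatch on ``cfg.model_kind``; always returns a list of labelled pairs."""
    out = _SIMULATORS[cfg.model_kind](cfg, rng)
    return out if isinstance(out, list) else [out]


def simulate_two_segment(
    alpha_pair: tuple[float, float],
    K_pair: tuple[float, float],
    T: int = 200,
    rng: np.random.Generator | None = None,
):
    """Two-segment trajectory with a single changepoint at the midpoint.

    Used for changepoint-sensitivity sweeps over the jump sizes
    |alpha_2 - alpha_1| and |K_2 - K_1|.  No field-of-view truncation, so
    the changepoint sits exactly at frame T // 2.
    """
    rng = rng if rng is not None else np.random.default_rng()
    mid = T // 2
    x = np.empty(T)
    y = np.empty(T)
    x[0] = y[0] = 0.0
    dx1, dy1 = simulate_segment(alpha_pair[0], K_pair[0], mid - 1, rng)
    x[1:mid] = np.cumsum(dx1)
    y[1:mid] = np.cumsum(dy1)
    dx2, dy2 = simulate_segment(alpha_pair[1], K_pair[1], T - mid, rng)
    x[mid:] = x[mid - 1] + np.cumsum(dx2)
    y[mid:] = y[mid - 1] + np.cumsum(dy2)
    alpha_t = np.where(np.arange(T) < mid, alpha_pair[0], alpha_pair[1])
    K_t = np.where(np.arange(T) < mid, K_pair[0], K_pair[1])
    state_t = np.array(
        [state_for(a, k) for a, k in zip(alpha_t, K_t)], dtype=int
    )
    # the midpoint is recorded as a changepoint even when the two segments
    # carry identical parameters (the delta = 0 sweep point): the detector
    # is then expected to find nothing, which scores Jaccard 0
    labels = LabelSeries(alpha_t, K_t, state_t, np.array([mid], dtype=int))
    return Trajectory("twoseg-0", x, y), labels


# ---------------------------------------------------------------------------
# dataset construction


#: the standard recipe: for each scenario a base group and a
#: directed-motion group (alpha restricted to [1.9, 2]); for the scenarios
#: with binding/transition changepoints, additional groups where only one
#: of alpha or K changes across changepoints.
DEFAULT_RECIPE: tuple[tuple[str, dict], ...] = tuple(
    [(kind, {}) for kind in MODEL_KINDS]
    + [(kind, {"alpha_range": (1.9, 2.0)}) for kind in MODEL_KINDS]
    + [(kind, {"alpha_only_change": True}) for kind in ("MSM", "DIM", "TCM")]
    + [(kind, {"k_only_change": True}) for kind in ("MSM", "DIM", "TCM")]
)

#: trajectories per recipe group at full scale (scale_factor = 1.0);
#: 13 groups x 400k = 5.2M total.
FULL_SCALE_PER_GROUP = 400_000


def _group_counts(total: int, n_groups: int) -> list[int]:
    """Deterministic split: floor share per group, remainder to the first groups."""
    base, extra = divmod(total, n_groups)
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


def build_dataset(
    scale_factor: float = 1e-3,
    seed: int = 0,
    recipe: Sequence[tuple[str, dict]] = DEFAULT_RECIPE,
    total: int | None = None,
):
    """Simulate a labelled dataset with a 60:20:20 train/val/test split.

    Parameters
    ----------
    scale_factor : fraction of the full-scale dataset (13 groups x 400 000
        trajectories) to generate; ignored when ``total`` is given.
    seed : master seed; the same seed reproduces the dataset exactly.
    recipe : (model_kind, config overrides) groups, equal counts per group.
    total : explicit total trajectory count.

    Returns
    -------
    dict with keys ``trajectories`` (list of Trajectory), ``labels``
    (list of LabelSeries), ``groups`` (recipe-group index per trajectory),
    ``split`` (per-trajectory 'train'/'val'/'test') and ``manifest``.
    """
    if total is None:
        total = max(int(round(FULL_SCALE_PER_GROUP * len(recipe) * scale_factor)), len(recipe))
    rng = np.random.default_rng(seed)
    counts = _group_counts(total, len(recipe))
    trajectories: list[Trajectory] = []
    labels: list[LabelSeries] = []
    group_ids: list[int] = []
    for gi, ((kind, overrides), count) in enumerate(zip(recipe, counts)):
        produced = 0
        while produced < count:
            cfg = SimConfig(model_kind=kind, **overrides)
            for traj, lab in simulate(cfg, rng):
                if produced >= count:
                    break
                traj.traj_id = f"g{gi}-{kind.lower()}-{produced}"
                trajectories.append(traj)
                labels.append(lab)
                group_ids.append(gi)
                produced += 1
    n = len(trajectories)
    order = rng.permutation(n)
    n_train = int(round(0.6 * n))
    n_val = int(round(0.2 * n))
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_val]] = "val"
    split[order[n_train + n_val :]] = "test"
    manifest = {
        "seed": int(seed),
        "total": int(n),
        "recipe": [
            {"model_kind": kind, "overrides": {k: _plain(v) for k, v in ov.items()}, "count": c}
            for (kind, ov), c in zip(recipe, counts)
        ],
        "split_ratio": [0.6, 0.2, 0.2],
    }
    return {
        "trajectories": trajectories,
        "labels": labels,
        "groups": np.array(group_ids),
        "split": split,
        "manifest": manifest,
    }


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
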