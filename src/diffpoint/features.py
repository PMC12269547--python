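"""Hand-crafted time-series features and training-time augmentations.

A trajectory (x(t), y(t)) of length T is converted into a 10 x T feature
matrix whose rows, in fixed order, are

=========  ==================================================================
x_hat      z-normalised x coordinate
y_hat      z-normalised y coordinate
d          displacement from the origin sqrt((x(t)-x(0))^2 + (y(t)-y(0))^2)
step_hat   z-normalised step length, step(t) = sqrt(dx(t)^2 + dy(t)^2)
theta      signed turning angle between consecutive displacement vectors
str        net displacement over path length of the normalised coordinates
str2       squared net displacement over summed squared normalised steps
F_xhat     log |delta x_hat|
F_yhat     log |delta y_hat|
F_stephat  log |delta step_hat|
=========  ==================================================================

``str``/``str2`` measure straightness: 1 for a perfectly directed path,
0 for a path back at its start.  Difference-based rows are naturally
shorter than T and are right-padded with zeros; z-normalisation uses the
population standard deviation, and a constant series normalises to zeros
(an immobile particle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "znorm",
    "compute_features",
    "augment",
    "Batch",
    "pad_and_batch",
]

FEATURE_NAMES = (
    "x_hat",
    "y_hat",
    "d",
    "step_hat",
    "theta",
    "str",
    "str2",
    "F_xhat",
    "F_yhat",
    "F_stephat",
)

_LOG_GUARD = 1e-12  # |delta| clamp before the log of difference features
T_MIN_AUG = 20  # shortest window the truncation augmentation may leave


def znorm(series: np.ndarray) -> np.ndarray:
    """(v - mean) / sd with population sd; a constant series maps to zeros."""
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        return v.copy()
    sd = v.std()
    if sd == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _pad_to(v: np.ndarray, T: int) -> np.ndarray:
    out = np.zeros(T)
    out[: v.size] = v
    return out


def compute_features(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """10 x T feature matrix for one trajectory (row order ``FEATURE_NAMES``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T = x.size
    if T < 2:
        raise ValueError("trajectory must have at least 2 frames")

    x_hat = znorm(x)
    y_hat = znorm(y)
    d = np.hypot(x - x[0], y - y[0])

    dx, dy = np.diff(x), np.diff(y)
    step = np.hypot(dx, dy)
    step_hat = znorm(step)

    # signed angle between consecutive displacement vectors, 0 where a
    # step has zero length
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    theta = np.arctan2(cross, dot)
    theta[(step[:-1] == 0) | (step[1:] == 0)] = 0.0

    # straightness on the normalised coordinates; index 0 has no path yet
    dxh, dyh = np.diff(x_hat), np.diff(y_hat)
    net = np.hypot(x_hat - x_hat[0], y_hat - y_hat[0])
    path = np.concatenate([[0.0], np.cumsum(np.hypot(dxh, dyh))])
    path2 = np.concatenate([[0.0], np.cumsum(dxh**2 + dyh**2)])
    with np.errstate(invalid="ignore", divide="ignore"):
        straight = np.where(path > 0, net / path, 0.0)
        straight2 = np.where(path2 > 0, net**2 / path2, 0.0)
    straight[0] = straight2[0] = 0.0

    def log_diff(v: np.ndarray) -> np.ndarray:
        return np.log(np.maximum(np.abs(np.diff(v)), _LOG_GUARD))

    rows = [
        x_hat,
        y_hat,
        d,
        _pad_to(step_hat, T),
        _pad_to(theta, T),
        straight,
        straight2,
        _pad_to(log_diff(x_hat), T),
        _pad_to(log_diff(y_hat), T),
        _pad_to(log_diff(step_hat), T),
    ]
    return np.stack(rows)


def augment(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    p: float = 0.3,
    noise_sigma: float = 0.1,
    return_window: bool = False,
):
    """Training-time coordinate augmentations, each fired independently.

    With probability ``p`` each: additive Gaussian localisation noise
    (sigma 0.1 px), rotation by a uniform angle, axis flips (x and/or y),
    and truncation to a random window of at least 20 frames.  Applied in
    that fixed order; features must be recomputed on the result.  With
    ``return_window`` the kept frame window ``(t1, t2)`` is also returned
    so per-frame labels can be sliced to match.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if rng.random() < p:
        x += rng.normal(0.0, noise_sigma, x.size)
        y += rng.normal(0.0, noise_sigma, y.size)
    if rng.random() < p:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(ang), np.sin(ang)
        x, y = c * x - s * y, s * x + c * y
    if rng.random() < p:
        if rng.random() < 0.5:
            x = -x
        if rng.random() < 0.5:
            y = -y
    T = x.size
    t1, t2 = 0, T
    if T > T_MIN_AUG and rng.random() < p:
        t1 = int(rng.integers(0, T - T_MIN_AUG + 1))
        t2 = int(rng.integers(t1 + T_MIN_AUG, T + 1))
        x, y = x[t1:t2], y[t1:t2]
    if return_window:
        return x, y, (t1, t2)
    return x, y


@dataclass
class Batch:
    """Zero-padded feature batch of shape (B, 10, T_max) plus true lengths."""

    data: np.ndarray
    lengths: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        """(B, T_max) boolean mask of real (non-padding) frames."""
        return np.arange(self.data.shape[2])[None, :] < self.lengths[:, None]


def pad_and_batch(features: list[np.ndarray]) -> Batch:
    """Right-pad feature matrices with zeros to the batch maximum length."""
    lengths = np.array([f.shape[1] for f in features], dtype=int)
    T_max = int(lengths.max())
    data = np.zeros((len(features), features[0].shape[0], T_max))
    for i, f in enumerate(features):
        data[i, :, : f.shape[1]] = f
    return Batch(data, lengths)
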