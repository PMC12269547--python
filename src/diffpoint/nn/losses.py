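"""Masked sequence losses (value + gradient with respect to predictions).

Each loss is a per-trajectory mean over *true* frames only (padding is
masked out), then averaged over the batch, so short and long trajectories
contribute equally.  K losses are computed in log10(K+1) space; callers
convert ground truth once at data-loading time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["masked_mae_loss", "masked_nll_loss", "class_weights"]


def masked_mae_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    """Mean absolute error; ``pred`` (B, T) or (B, T, 1), ``mask`` (B, T) bool.

    Returns ``(loss, dpred)`` with ``dpred`` shaped like ``pred``.
    """
    squeeze = pred.ndim == 3
    p = pred[..., 0] if squeeze else pred
    diff = p - target
    m = mask.astype(float)
    lengths = m.sum(axis=1)
    per_traj = (np.abs(diff) * m).sum(axis=1) / lengths
    loss = float(per_traj.mean())
    B = p.shape[0]
    dp = np.sign(diff) * m / lengths[:, None] / B
    return loss, (dp[..., None] if squeeze else dp)


def masked_nll_loss(logp: np.ndarray, labels: np.ndarray, mask: np.ndarray,
                    weights: np.ndarray | None = None):
    """Class-weighted negative log-likelihood.

    ``logp`` (B, T, C) per-frame log-probabilities, ``labels`` (B, T) int,
    ``weights`` (C,) or None for unit weights.  Returns ``(loss, dlogp)``.
    """
    B, T, C = logp.shape
    if weights is None:
        weights = np.ones(C)
    lab = np.where(mask, labels, 0)
    w = weights[lab] * mask
    picked = np.take_along_axis(logp, lab[..., None], axis=2)[..., 0]
    lengths = mask.sum(axis=1).astype(float)
    per_traj = (-w * picked).sum(axis=1) / lengths
    loss = float(per_traj.mean())
    dlogp = np.zeros_like(logp)
    coeff = -w / lengths[:, None] / B
    np.put_along_axis(dlogp, lab[..., None], coeff[..., None], axis=2)
    return loss, dlogp


def class_weights(labels: list[np.ndarray], n_classes: int = 4) -> np.ndarray:
    """Inverse-frequency class weights from training labels, mean-normalised.

    Classes absent from the training set get weight 0 (they can never be
    a target, so their weight is irrelevant; zero avoids an infinity).
    """
    counts = np.zeros(n_classes)
    for lab in labels:
        counts += np.bincount(np.asarray(lab, dtype=int), minlength=n_classes)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts[present].sum() / counts[present]
    if present.any():
        w /= w[present].mean()
    return w
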