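"""Inference: feature extraction (no augmentation) + one forward pass.

Predictions for K live in log10(K+1) space (nominal range [0, 6]); state
predictions are per-frame log-probabilities over the four classes, with
the hard label taken as the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..features import compute_features, pad_and_batch
from ..simulate import Trajectory
from .model import SequenceModel

__all__ = ["PredictionSeries", "predict_series", "predict_batch", "predict_pointwise"]


@dataclass
class PredictionSeries:
    """Per-frame predictions for one trajectory (all arrays length T)."""

    alpha_hat: np.ndarray | None = None
    logK_hat: np.ndarray | None = None
    state_logprobs: np.ndarray | None = None  # (T, 4)

    @property
    def state_hat(self) -> np.ndarray | None:
        if self.state_logprobs is None:
            return None
        return np.argmax(self.state_logprobs, axis=1)


def predict_series(model: SequenceModel, trajectory: Trajectory) -> np.ndarray:
    """Predicted series for one trajectory: (T,) regression or (T, 4) log-probs."""
    return predict_batch(model, [trajectory])[0]


def predict_batch(
    model: SequenceModel, trajectories: list[Trajectory], batch_size: int = 64
) -> list[np.ndarray]:
    """Batched inference; identical to per-trajectory inference up to padding."""
    out: list[np.ndarray] = []
    for i in range(0, len(trajectories), batch_size):
        chunk = trajectories[i : i + batch_size]
        batch = pad_and_batch([compute_features(t.x, t.y) for t in chunk])
        pred = model.forward(batch.data, batch.lengths, training=False)
        for j, t in enumerate(chunk):
            T = len(t)
            out.append(pred[j, :T, 0] if pred.shape[2] == 1 else pred[j, :T])
    return out


def predict_pointwise(
    models: dict[str, SequenceModel], trajectory: Trajectory
) -> PredictionSeries:
    """Run whichever per-variable models are provided on one trajectory."""
    series = PredictionSeries()
    if "alpha" in models:
        series.alpha_hat = predict_series(models["alpha"], trajectory)
    if "K" in models:
        series.logK_hat = predict_series(models["K"], trajectory)
    if "state" in models:
        series.state_logprobs = predict_series(models["state"], trajectory)
    return series
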