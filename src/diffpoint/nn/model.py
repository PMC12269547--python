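"""The per-variable sequence labelling network.

Three stacked bidirectional-LSTM blocks with skip connections: each block
emits 128 features per frame (64 per direction), applies a rectified
linear activation, concatenates the result with the block's own input and
layer-normalises.  Feature widths therefore grow 10 -> 138 -> 266 -> 394.
The first two blocks stack two LSTM layers with 10% inter-layer dropout;
the third has a single layer.  A linear head maps the 394-wide frames to
one output (regression of alpha, or of K in log10(K+1) space) or to four
log-probabilities (state classification, via log-softmax).

With 64 hidden units per direction the regression network has 513,991
trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BiLSTMLayer, LayerNorm, Linear, Param

__all__ = ["NetConfig", "Block", "SequenceModel", "build_model"]

TASKS = ("alpha", "K", "state")


@dataclass
class NetConfig:
    task: str = "alpha"
    feature_dim: int = 10
    hidden: int = 64  # per direction; each biLSTM emits 2*hidden per frame
    block_layers: tuple[int, ...] = (2, 2, 1)
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")

    @property
    def out_dim(self) -> int:
        return 4 if self.task == "state" else 1

    @property
    def classification(self) -> bool:
        return self.task == "state"


class Block:
    """biLSTM stack -> ReLU -> concat with block input -> layer norm."""

    def __init__(self, in_dim: int, n_layers: int, hidden: int, dropout: float,
                 rng: np.random.Generator):
        self.layers = []
        d = in_dim
        for _ in range(n_layers):
            self.layers.append(BiLSTMLayer(d, hidden, rng))
            d = 2 * hidden
        self.norm = LayerNorm(2 * hidden + in_dim)
        self.dropout = dropout
        self.out_dim = 2 * hidden + in_dim
        self._cache = None

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.norm.params())
        return out

    def forward(self, x, lengths, training=False, rng=None):
        h = x
        masks = []
        for li, layer in enumerate(self.layers):
            h = layer.forward(h, lengths)
            if training and self.dropout > 0 and li < len(self.layers) - 1:
                keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * keep
                masks.append(keep)
            else:
                masks.append(None)
        relu_mask = h > 0
        cat = np.concatenate([h * relu_mask, x], axis=2)
        self._cache = (relu_mask, masks)
        return self.norm.forward(cat)

    def backward(self, dy):
        relu_mask, masks = self._cache
        dcat = self.norm.backward(dy)
        width = relu_mask.shape[2]
        dh = dcat[:, :, :width] * relu_mask
        dx_skip = dcat[:, :, width:]
        for layer, keep in zip(reversed(self.layers), reversed(masks)):
            if keep is not None:
                dh = dh * keep
            dh = layer.backward(dh)
        return dh + dx_skip


class SequenceModel:
    """Per-frame labeller: (B, 10, T) features -> (B, T, out) predictions."""

    def __init__(self, config: NetConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.blocks = []
        d = config.feature_dim
        for n_layers in config.block_layers:
            block = Block(d, n_layers, config.hidden, config.dropout, rng)
            self.blocks.append(block)
            d = block.out_dim
        self.head = Linear(d, config.out_dim, rng)
        self._softmax = None

    # -- parameters --------------------------------------------------------

    def params(self) -> list[Param]:
        out = []
        for block in self.blocks:
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for i, p in enumerate(params):
            v = np.asarray(state[f"p{i}"], dtype=float)
            if v.shape != p.value.shape:
                raise ValueError("checkpoint does not match the architecture")
            p.value[...] = v

    # -- forward / backward -------------------------------------------------

    def forward(self, batch_data: np.ndarray, lengths: np.ndarray,
                training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """``batch_data`` has shape (B, 10, T); returns (B, T, out_dim)."""
        x = np.ascontiguousarray(np.transpose(batch_data, (0, 2, 1)))
        for block in self.blocks:
            x = block.forward(x, lengths, training=training, rng=rng)
        out = self.head.forward(x)
        if self.config.classification:
            # log-softmax over the class axis
            m = out.max(axis=-1, keepdims=True)
            lse = m + np.log(np.exp(out - m).sum(axis=-1, keepdims=True))
            logp = out - lse
            self._softmax = np.exp(logp)
            return logp
        return out

    def backward(self, dout: np.ndarray) -> None:
        if self.config.classification:
            dout = dout - self._softmax * dout.sum(axis=-1, keepdims=True)
        dx = self.head.backward(dout)
        for block in reversed(self.blocks):
            dx = block.backward(dx)


def build_model(task: str, seed: int = 0, **overrides) -> SequenceModel:
    """Construct the network for one output variable ('alpha', 'K', 'state')."""
    config = NetConfig(task=task, **overrides)
    return SequenceModel(config, np.random.default_rng(seed))
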