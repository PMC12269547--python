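"""Training loop: Adam, plateau learning-rate schedule, best-epoch checkpoint.

One network is trained per output variable.  Batches of 32 for at most 30
epochs; validation loss is evaluated every epoch (and once before
training, as the improvement baseline) and the weights of the
lowest-validation-loss epoch are kept.  If validation loss fails to
improve for five consecutive epochs the learning rate drops by a factor
of ten.  K targets are converted to log10(K+1) once, at data loading.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..features import augment, compute_features, pad_and_batch
from ..simulate import LabelSeries, Trajectory
from .losses import class_weights, masked_mae_loss, masked_nll_loss
from .model import NetConfig, SequenceModel
from .optim import Adam

__all__ = ["TrainConfig", "TrainResult", "train", "target_series",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 30
    lr: float = 1e-3
    weight_decay: float = 2e-6
    patience: int = 5
    lr_factor: float = 0.1
    augment: bool = True
    augment_prob: float = 0.3
    seed: int = 0


@dataclass
class TrainResult:
    model: SequenceModel
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    weights: np.ndarray | None = None  # state-task class weights


def target_series(labels: LabelSeries, task: str) -> np.ndarray:
    """Ground-truth series for one task; K in log10(K+1) space."""
    if task == "alpha":
        return labels.alpha.astype(float)
    if task == "K":
        return np.log10(labels.K + 1.0)
    if task == "state":
        return labels.state.astype(int)
    raise ValueError(f"unknown task {task!r}")


def _pad_targets(targets: list[np.ndarray], T_max: int, classification: bool):
    out = np.zeros((len(targets), T_max), dtype=int if classification else float)
    for i, t in enumerate(targets):
        out[i, : t.size] = t
    return out


def _batch_loss(model, feats, targs, task, weights, training, rng):
    batch = pad_and_batch(feats)
    targets = _pad_targets(targs, batch.data.shape[2], task == "state")
    out = model.forward(batch.data, batch.lengths, training=training, rng=rng)
    if task == "state":
        loss, dout = masked_nll_loss(out, targets, batch.mask, weights)
    else:
        loss, dout = masked_mae_loss(out, targets, batch.mask)
    return loss, dout


def _eval_loss(model, feats, targs, task, weights, batch_size):
    total, n = 0.0, 0
    for i in range(0, len(feats), batch_size):
        fs, ts = feats[i : i + batch_size], targs[i : i + batch_size]
        loss, _ = _batch_loss(model, fs, ts, task, weights, False, None)
        total += loss * len(fs)
        n += len(fs)
    return total / max(n, 1)


def train(
    dataset: dict,
    task: str,
    train_config: TrainConfig | None = None,
    net_config: NetConfig | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train one per-variable model on a ``build_dataset``-style dict.

    ``dataset`` needs keys ``trajectories``, ``labels`` and ``split``
    (train/val membership); the test split is untouched.
    """
    cfg = train_config or TrainConfig()
    net_cfg = net_config or NetConfig(task=task)
    if net_cfg.task != task:
        raise ValueError("net_config.task does not match task")
    rng = np.random.default_rng(cfg.seed)
    model = SequenceModel(net_cfg, rng)

    split = np.asarray(dataset["split"])
    trajs: list[Trajectory] = dataset["trajectories"]
    labels: list[LabelSeries] = dataset["labels"]
    idx_train = np.flatnonzero(split == "train")
    idx_val = np.flatnonzero(split == "val")
    if idx_train.size == 0 or idx_val.size == 0:
        raise ValueError("dataset must contain both train and val trajectories")

    raw_targets = [target_series(lab, task) for lab in labels]
    weights = None
    if task == "state":
        weights = class_weights([raw_targets[i] for i in idx_train])

    val_feats = [compute_features(trajs[i].x, trajs[i].y) for i in idx_val]
    val_targs = [raw_targets[i] for i in idx_val]

    opt = Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_val = _eval_loss(model, val_feats, val_targs, task, weights, cfg.batch_size)
    best_state = model.state_dict()
    best_epoch = 0
    bad_epochs = 0
    rows = [{"epoch": 0, "train_loss": np.nan, "val_loss": best_val, "lr": opt.lr}]
    if verbose:
        print(f"epoch 0 (untrained) val_loss={best_val:.4f}")

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(idx_train)
        train_loss_sum, seen = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            chunk = order[start : start + cfg.batch_size]
            feats, targs = [], []
            for i in chunk:
                x, y = trajs[i].x, trajs[i].y
                t = raw_targets[i]
                if cfg.augment:
                    x, y, (t1, t2) = augment(
                        x, y, rng, p=cfg.augment_prob, return_window=True
                    )
                    t = t[t1:t2]
                feats.append(compute_features(x, y))
                targs.append(t)
            model.zero_grad()
            loss, dout = _batch_loss(model, feats, targs, task, weights, True, rng)
            model.backward(dout)
            opt.step()
            train_loss_sum += loss * len(chunk)
            seen += len(chunk)

        val_loss = _eval_loss(model, val_feats, val_targs, task, weights, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(
                f"validation loss became non-finite at epoch {epoch}; "
                "check inputs or lower the learning rate"
            )
        rows.append(
            {"epoch": epoch, "train_loss": train_loss_sum / seen,
             "val_loss": val_loss, "lr": opt.lr}
        )
        if verbose:
            print(f"epoch {epoch} train={train_loss_sum / seen:.4f} "
                  f"val={val_loss:.4f} lr={opt.lr:g}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                opt.lr *= cfg.lr_factor
                bad_epochs = 0

    model.load_state_dict(best_state)
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss", "lr"])
    return TrainResult(model, history, best_epoch, best_val, weights)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, result: TrainResult,
                    train_config: TrainConfig | None = None,
                    extra: dict | None = None) -> Path:
    """Persist weights + configuration as a single .npz file."""
    path = Path(path)
    meta = {
        "net_config": {**asdict(result.model.config)},
        "train_config": asdict(train_config) if train_config else None,
        "best_epoch": result.best_epoch,
        "best_val_loss": result.best_val_loss,
        "extra": extra or {},
    }
    arrays = result.model.state_dict()
    if result.weights is not None:
        arrays["class_weights"] = result.weights
    np.savez(path, __meta__=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[SequenceModel, dict]:
    """Rebuild the model (weights loaded) and return it with its metadata."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        nc = meta["net_config"]
        nc["block_layers"] = tuple(nc["block_layers"])
        model = SequenceModel(NetConfig(**nc))
        state = {k: data[k] for k in data.files if k.startswith("p")}
        model.load_state_dict(state)
        if "class_weights" in data.files:
            meta["class_weights"] = data["class_weights"].copy()
    return model, meta
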