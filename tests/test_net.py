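"""Network architecture, losses, gradients, training loop, inference."""

import numpy as np
import pytest

from diffpoint.features import compute_features, pad_and_batch
from diffpoint.nn import (
    Adam,
    NetConfig,
    SequenceModel,
    TrainConfig,
    build_model,
    class_weights,
    load_checkpoint,
    masked_mae_loss,
    masked_nll_loss,
    save_checkpoint,
    train,
)
from diffpoint.nn.predict import predict_batch, predict_series
from diffpoint.simulate import SimConfig, build_dataset, simulate_ssm


# ---------------------------------------------------------------------------
# architecture


def test_regression_parameter_count_matches_derivation():
    assert build_model("alpha").parameter_count() == 513_991
    assert build_model("K").parameter_count() == 513_991


def test_classification_head_adds_1185_parameters():
    assert build_model("state").parameter_count() - build_model("alpha").parameter_count() == 3 * 395


def test_forward_output_shapes(rng):
    m = build_model("alpha", seed=1)
    x = rng.standard_normal((3, 10, 25))
    lengths = np.array([25, 20, 22])
    out = m.forward(x, lengths)
    assert out.shape == (3, 25, 1)
    mc = build_model("state", seed=1)
    logp = mc.forward(x, lengths)
    assert logp.shape == (3, 25, 4)
    np.testing.assert_allclose(np.exp(logp).sum(axis=-1), 1.0, atol=1e-6)


def test_unknown_task_rejected():
    with pytest.raises(ValueError):
        build_model("momentum")


# ---------------------------------------------------------------------------
# losses


def test_mae_loss_examples(rng):
    gt = rng.standard_normal((2, 10))
    mask = np.ones((2, 10), bool)
    assert masked_mae_loss(gt.copy(), gt, mask)[0] == 0.0
    assert masked_mae_loss(gt + 0.5, gt, mask)[0] == pytest.approx(0.5)
    # per-trajectory MAEs 0.2 and 0.4 -> batch mean 0.3
    pred = gt + np.array([[0.2], [0.4]])
    assert masked_mae_loss(pred, gt, mask)[0] == pytest.approx(0.3)


def test_K_loss_in_log_space():
    # log10(K_p + 1) = 2 vs log10(K_g + 1) = 1 at every frame -> 1
    mask = np.ones((1, 5), bool)
    assert masked_mae_loss(np.full((1, 5), 2.0), np.full((1, 5), 1.0), mask)[0] == 1.0
    # gt K = 0, pred K = 9: log10(10) - log10(1) = 1
    assert masked_mae_loss(
        np.full((1, 5), np.log10(9 + 1.0)), np.full((1, 5), np.log10(0 + 1.0)), mask
    )[0] == pytest.approx(1.0)


def test_nll_loss_examples():
    mask = np.ones((1, 6), bool)
    labels = np.zeros((1, 6), dtype=int)
    perfect = np.full((1, 6, 4), -50.0)
    perfect[..., 0] = 0.0
    assert masked_nll_loss(perfect, labels, mask)[0] == 0.0
    uniform = np.full((1, 6, 4), np.log(0.25))
    assert masked_nll_loss(uniform, labels, mask)[0] == pytest.approx(np.log(4))
    w = np.array([2.0, 1.0, 1.0, 1.0])
    assert masked_nll_loss(uniform, labels, mask, w)[0] == pytest.approx(2 * np.log(4))


def test_class_weights_inverse_frequency():
    labels = [np.array([2, 2, 2, 2, 2, 2, 0, 0, 3])]
    w = class_weights(labels)
    assert w[2] < w[0] < w[3]
    assert w[1] == 0.0  # absent class
    present = w[w > 0]
    assert present.mean() == pytest.approx(1.0)


def test_loss_masking_invariance(rng):
    """Appending padded frames never changes any loss value."""
    m = build_model("alpha", seed=3)
    x = rng.standard_normal((2, 10, 15))
    lengths = np.array([15, 12])
    gt = rng.standard_normal((2, 15))
    mask = np.arange(15)[None, :] < lengths[:, None]
    loss1, _ = masked_mae_loss(m.forward(x, lengths), gt, mask)
    xp = np.concatenate([x, np.zeros((2, 10, 5))], axis=2)
    gtp = np.concatenate([gt, np.zeros((2, 5))], axis=1)
    maskp = np.arange(20)[None, :] < lengths[:, None]
    loss2, _ = masked_mae_loss(m.forward(xp, lengths), gtp, maskp)
    assert loss1 == pytest.approx(loss2, abs=1e-9)


# ---------------------------------------------------------------------------
# gradients


def numeric_grad_check(model, loss_fn, rng, n_checks=12, eps=1e-6):
    loss0, dout = loss_fn()
    model.zero_grad()
    model.backward(dout)
    worst = 0.0
    for p in model.params():
        idx = tuple(rng.integers(0, s) for s in p.value.shape)
        orig = p.value[idx]
        p.value[idx] = orig + eps
        lp, _ = loss_fn()
        p.value[idx] = orig - eps
        lm, _ = loss_fn()
        p.value[idx] = orig
        worst = max(worst, abs((lp - lm) / (2 * eps) - p.grad[idx]))
    return worst


def test_gradients_match_finite_differences(rng):
    cfg = NetConfig(task="alpha", hidden=4, block_layers=(2, 1), dropout=0.0)
    m = SequenceModel(cfg, np.random.default_rng(2))
    x = rng.standard_normal((2, 10, 7))
    lengths = np.array([7, 5])
    gt = rng.standard_normal((2, 7))
    mask = np.arange(7)[None, :] < lengths[:, None]
    err = numeric_grad_check(m, lambda: masked_mae_loss(m.forward(x, lengths), gt, mask), rng)
    assert err < 1e-7


def test_classification_gradients_match_finite_differences(rng):
    cfg = NetConfig(task="state", hidden=3, block_layers=(1, 1), dropout=0.0)
    m = SequenceModel(cfg, np.random.default_rng(4))
    x = rng.standard_normal((2, 10, 6))
    lengths = np.array([6, 4])
    labels = rng.integers(0, 4, (2, 6))
    mask = np.arange(6)[None, :] < lengths[:, None]
    w = np.array([2.0, 1.0, 0.5, 1.5])
    err = numeric_grad_check(
        m, lambda: masked_nll_loss(m.forward(x, lengths), labels, mask, w), rng
    )
    assert err < 1e-7


def test_losses_decrease_on_overfit_set():
    """50 Adam steps on a 64-trajectory set shrink the training loss."""
    rng = np.random.default_rng(0)
    trajs, labs = [], []
    for i in range(64):
        t, l = simulate_ssm(SimConfig("SSM", T=20), rng)
        trajs.append(t)
        labs.append(l)
    feats = [compute_features(t.x, t.y) for t in trajs]
    targets = [l.alpha for l in labs]
    m = build_model("alpha", seed=5)
    opt = Adam(m.params())
    losses = []
    for step in range(50):
        sel = rng.permutation(64)[:32]
        batch = pad_and_batch([feats[i] for i in sel])
        gt = np.zeros((32, batch.data.shape[2]))
        for j, i in enumerate(sel):
            gt[j, : targets[i].size] = targets[i]
        out = m.forward(batch.data, batch.lengths, training=True, rng=rng)
        loss, dout = masked_mae_loss(out, gt, batch.mask)
        m.zero_grad()
        m.backward(dout)
        opt.step()
        losses.append(loss)
    assert np.mean(losses[-10:]) < 0.7 * np.mean(losses[:10])


# ---------------------------------------------------------------------------
# training loop / checkpoints / inference


@pytest.fixture(scope="module")
def tiny_run(tmp_path_factory):
    ds = build_dataset(total=120, seed=21, recipe=[("SSM", {"T_range": (20, 30)})])
    tc = TrainConfig(max_epochs=2, seed=3)
    result = train(ds, "alpha", tc)
    path = tmp_path_factory.mktemp("ckpt") / "alpha.npz"
    save_checkpoint(path, result, tc, extra={"dataset_seed": 21})
    return ds, result, path


def test_training_log_and_best_epoch(tiny_run):
    _, result, _ = tiny_run
    h = result.history
    assert list(h.columns) == ["epoch", "train_loss", "val_loss", "lr"]
    assert len(h) == 3  # pre-training baseline + 2 epochs
    assert result.best_val_loss == pytest.approx(h["val_loss"].min())
    assert result.best_epoch == int(h.loc[h["val_loss"].idxmin(), "epoch"])


def test_checkpoint_roundtrip_preserves_predictions(tiny_run):
    ds, result, path = tiny_run
    model2, meta = load_checkpoint(path)
    assert meta["extra"]["dataset_seed"] == 21
    traj = ds["trajectories"][0]
    np.testing.assert_allclose(
        predict_series(result.model, traj), predict_series(model2, traj), atol=1e-12
    )


def test_batched_inference_matches_single(tiny_run):
    ds, result, _ = tiny_run
    trajs = ds["trajectories"][:8]
    batched = predict_batch(result.model, trajs, batch_size=8)
    for t, b in zip(trajs, batched):
        single = predict_series(result.model, t)
        assert single.size == len(t)
        np.testing.assert_allclose(single, b, atol=1e-5)


def test_train_rejects_mismatched_config(tiny_run):
    ds, _, _ = tiny_run
    with pytest.raises(ValueError):
        train(ds, "alpha", net_config=NetConfig(task="K"))
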