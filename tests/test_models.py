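import numpy as np
import pytest

import pdgait.models as models
import pdgait.nn as nn
from pdgait.errors import TrainingDiverged
from pdgait.models import (
    ConvNet1D,
    ConvNetConfig,
    TimeSpatialTransformer,
    TrainConfig,
    TransformerConfig,
    build_model,
    predict_segments,
    selu,
    train,
)
from pdgait.nn import SELU_ALPHA, SELU_LAMBDA, softmax_cross_entropy
from pdgait.windowing import SegmentBatch

# ---------------------------------------------------------------- activation


def test_selu_matches_closed_form_on_grid():
    x = np.linspace(-10, 10, 1000)
    expected = np.where(x > 0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * (np.exp(x) - 1))
    assert np.allclose(selu(x), expected, atol=1e-12)


def test_selu_anchor_values():
    assert selu(0.0) == 0.0
    assert np.isclose(selu(1.0), 1.05070, atol=1e-5)
    assert np.isclose(selu(-50.0), -SELU_LAMBDA * SELU_ALPHA, atol=1e-6)  # -> -1.7581


# ---------------------------------------------------------------- architecture


def test_parameter_counts_are_stable():
    m = build_model("convnet", rng=np.random.default_rng(0))
    t = build_model("transformer", rng=np.random.default_rng(0))
    assert m.n_params == 135_674
    assert t.n_params == 24_772


def test_convnet_per_channel_feature_width_is_50(rng):
    m = ConvNet1D(ConvNetConfig(), rng)
    X = rng.normal(0, 1, (3, 100, 18)).astype(np.float32)
    feats = m.branch.forward(np.asarray(X))
    assert feats.shape == (3, 18 * 50)


def test_convnet_outputs_probabilities_and_handles_zeros(rng):
    m = ConvNet1D(ConvNetConfig(), rng)
    probs = m.predict_proba(np.zeros((5, 100, 18), dtype=np.float32))
    assert probs.shape == (5, 4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(np.isfinite(probs))


def test_convnet_rejects_wrong_window(rng):
    m = ConvNet1D(ConvNetConfig(), rng)
    with pytest.raises(ValueError):
        m.forward(np.zeros((2, 99, 18), dtype=np.float32))


def test_shared_and_separate_branch_modes_both_run(rng):
    for shared in (False, True):
        cfg = ConvNetConfig(n_channels=4, shared_branches=shared)
        m = ConvNet1D(cfg, rng)
        out = m.forward(rng.normal(0, 1, (3, 100, 4)).astype(np.float32))
        assert out.shape == (3, 4)


_SMALL_T = dict(window=30, n_channels=6, key_dim=8, num_heads=2, d_embed=8,
                head_hidden=10, dropout_rate=0.0)


def test_transformer_spatial_encoder_attends_over_all_channels(rng):
    m = TimeSpatialTransformer(TransformerConfig(**_SMALL_T), rng)
    m.forward(rng.normal(0, 1, (2, 30, 6)).astype(np.float32))
    att = m.spatial_blocks[0].mha.last_attention
    assert att.shape[-2:] == (6, 6)  # one token per sensor channel
    assert m.spatial_tokens == 6


def test_transformer_positional_encoding_contract(rng):
    X = rng.normal(0, 1, (2, 30, 6)).astype(np.float32)
    perm = np.array([3, 1, 5, 0, 2, 4])
    off = TimeSpatialTransformer(
        TransformerConfig(**_SMALL_T, positional_encoding=False), np.random.default_rng(0)
    )
    out_a = off.forward(X)
    out_b = off.forward(X[:, :, perm])
    assert np.allclose(out_a, out_b, atol=1e-4)  # sensor order irrelevant without PE
    on = TimeSpatialTransformer(
        TransformerConfig(**_SMALL_T, positional_encoding=True), np.random.default_rng(0)
    )
    assert not np.allclose(on.forward(X), on.forward(X[:, :, perm]), atol=1e-4)


def test_transformer_outputs_probability_vector(rng):
    m = TimeSpatialTransformer(TransformerConfig(**_SMALL_T), rng)
    probs = m.predict_proba(rng.normal(0, 1, (3, 30, 6)).astype(np.float32))
    assert probs.shape == (3, 4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


# ---------------------------------------------------------------- gradients


def _numeric_grad_check(make_model, X, y, rng, n_per_param=3):
    model = make_model()
    for p in model.params():  # nudge off exact zeros to dodge the SELU kink
        p.value += rng.normal(0, 1e-3, p.value.shape)
    logits = model.forward(X.copy())
    _, d = softmax_cross_entropy(logits, y)
    for p in model.params():
        p.grad[...] = 0
    model.backward(d)
    worst = 0.0
    for p in model.params():
        flat, g = p.value.reshape(-1), p.grad.reshape(-1)
        for i in rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False):
            old, eps = flat[i], 1e-6
            flat[i] = old + eps
            l1, _ = softmax_cross_entropy(model.forward(X.copy()), y)
            flat[i] = old - eps
            l2, _ = softmax_cross_entropy(model.forward(X.copy()), y)
            flat[i] = old
            num, ana = (l1 - l2) / (2 * eps), g[i]
            if abs(num - ana) < 1e-6:  # below finite-difference noise
                continue
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
    return worst


@pytest.mark.parametrize("kind", ["convnet", "convnet_shared", "transformer"])
def test_backward_matches_numerical_gradients(kind, monkeypatch):
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    monkeypatch.setattr(models, "DTYPE", np.float64)
    rng = np.random.default_rng(42)
    if kind.startswith("convnet"):
        cfg = ConvNetConfig(window=20, n_channels=3, conv_specs=((4, 3),) * 3 + ((1, 3),),
                            fusion=(10, 6), dense_per_channel=5, dropout_rate=0.0,
                            shared_branches=kind.endswith("shared"))
        make = lambda: ConvNet1D(cfg, np.random.default_rng(1))
        X, y = rng.normal(0, 1, (6, 20, 3)), rng.integers(0, 4, 6)
    else:
        cfg = TransformerConfig(window=12, n_channels=3, key_dim=5, num_heads=2,
                                d_embed=6, head_hidden=7, dropout_rate=0.0)
        make = lambda: TimeSpatialTransformer(cfg, np.random.default_rng(1))
        X, y = rng.normal(0, 1, (5, 12, 3)), rng.integers(0, 4, 5)
    assert _numeric_grad_check(make, X, y, rng) < 1e-4


# ---------------------------------------------------------------- training


def _toy_batches(rng, n_train=60, n_val=20):
    """Linearly separable 2-class toy: class 1 has 3x the amplitude."""

    def make(n, subject):
        X = rng.normal(0, 1, (n, 100, 2)).astype(np.float32)
        y = rng.integers(0, 2, n)
        X[y == 1] *= 3.0
        prov = [(subject, "01", i) for i in range(n)]
        return SegmentBatch(X, y, prov)

    return make(n_train, "train_subj"), make(n_val, "val_subj")


def _toy_model(seed=0):
    cfg = ConvNetConfig(n_channels=2, conv_specs=((4, 3), (4, 3), (4, 3), (1, 3)),
                        fusion=(16, 8), dense_per_channel=8, batch_size=30)
    return ConvNet1D(cfg, np.random.default_rng(seed))


def test_training_reduces_loss_on_separable_toy(rng):
    train_b, val_b = _toy_batches(rng)
    hist = train(_toy_model(), train_b, val_b,
                 TrainConfig(learning_rate=3e-3, max_epochs=30, patience=30, seed=0))
    assert hist[-1]["loss"] < hist[0]["loss"]
    assert hist[-1]["val_acc"] >= 0.9


def test_early_stopping_triggers_within_patience_plus_one(rng):
    train_b, val_b = _toy_batches(rng, 30, 10)
    # zero learning rate -> validation loss exactly constant -> stop early
    hist = train(_toy_model(), train_b, val_b,
                 TrainConfig(learning_rate=1e-12, max_epochs=50, patience=3, seed=0))
    assert len(hist) <= 3 + 1


def test_training_is_deterministic_under_seed(rng):
    train_b, val_b = _toy_batches(rng, 30, 10)
    h1 = train(_toy_model(seed=5), train_b, val_b,
               TrainConfig(learning_rate=1e-3, max_epochs=4, patience=4, seed=9))
    h2 = train(_toy_model(seed=5), train_b, val_b,
               TrainConfig(learning_rate=1e-3, max_epochs=4, patience=4, seed=9))
    assert h1[-1]["loss"] == h2[-1]["loss"]
    assert h1[-1]["val_loss"] == h2[-1]["val_loss"]


def test_train_rejects_subject_overlap(rng):
    train_b, _ = _toy_batches(rng, 20, 10)
    with pytest.raises(AssertionError):
        train(_toy_model(), train_b, train_b, TrainConfig(max_epochs=1))


def test_predict_segments_consistency(rng):
    train_b, val_b = _toy_batches(rng, 20, 10)
    model = _toy_model()
    preds, probs = predict_segments(model, val_b)
    assert len(preds) == len(val_b)
    assert np.array_equal(preds, probs.argmax(axis=1))
    preds2, _ = predict_segments(model, val_b)
    assert np.array_equal(preds, preds2)  # inference is deterministic


def test_config_validation():
    with pytest.raises(ValueError):
        ConvNetConfig(conv_specs=((8, 4),))  # even kernel
    with pytest.raises(ValueError):
        TransformerConfig(num_heads=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
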