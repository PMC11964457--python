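"""The two severity classifiers and their training loop.

**1D-ConvNet** — each of the 18 sensor channels runs through its own small
convolutional branch on a (100, 1) window: conv(8,3) → conv(16,3) →
maxpool(2) → conv(16,3) → conv(1,3) → maxpool(2) → flatten → dense(50),
all SELU.  The 18 fifty-dimensional branch outputs are concatenated and
fused through dense(100) → dense(20) with dropout into a 4-class softmax.
Branches use separate weights by default (a shared-weights variant is
config-switchable).

**Time–spatial transformer** — each channel's window passes through a
pre-norm encoder block (layer norm → 2-head self-attention with key
dimension 100 → dropout → residual, then layer norm → feed-forward →
residual).  The per-channel encoder output is fused by a fully connected
layer into one embedding per channel; the stack of 18 channel embeddings,
plus a sinusoidal positional encoding on the sensor index, passes through an
identical spatial encoder block, is mean-pooled over sensors and classified
by two fully connected layers.  With the positional encoding off the model
is invariant to sensor order; with it on the sensor layout matters.

Training minimises categorical cross-entropy with Nadam (beta1 = 0.9,
beta2 = 0.999) and early-stops on validation loss (stop when it fails to
improve by ``min_delta`` for ``patience`` epochs; best-epoch weights are
restored).  Inputs are standardised per channel using training-fold
statistics stored on the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import TrainingDiverged
from .nn import (
    DTYPE,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GroupedConv1D,
    GroupedDense,
    GroupedMaxPool1D,
    LayerNorm,
    MaxPool1D,
    MultiHeadSelfAttention,
    Nadam,
    Param,
    selu,
    softmax_cross_entropy,
    _softmax,
)
from .windowing import SegmentBatch

__all__ = [
    "ConvNetConfig",
    "TransformerConfig",
    "TrainConfig",
    "ConvNet1D",
    "TimeSpatialTransformer",
    "build_convnet",
    "build_time_spatial_transformer",
    "build_model",
    "train",
    "predict_segments",
    "selu",
]


@dataclass(frozen=True)
class ConvNetConfig:
    conv_specs: tuple[tuple[int, int], ...] = ((8, 3), (16, 3), (16, 3), (1, 3))
    pool_after: tuple[int, ...] = (2, 4)  # 1-based conv indices followed by maxpool(2)
    pool_size: int = 2
    dense_per_channel: int = 50
    fusion: tuple[int, int] = (100, 20)
    dropout_rate: float = 0.1
    window: int = 100
    n_channels: int = 18
    n_classes: int = 4
    batch_size: int = 200
    shared_branches: bool = False

    def __post_init__(self) -> None:
        if any(k % 2 == 0 for _, k in self.conv_specs):
            raise ValueError("kernel sizes must be odd")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TransformerConfig:
    num_blocks: int = 1
    key_dim: int = 100
    num_heads: int = 2
    dropout_rate: float = 0.3
    window: int = 100
    n_channels: int = 18
    n_classes: int = 4
    batch_size: int = 100
    d_embed: int = 16  # per-channel embedding entering the spatial encoder
    head_hidden: int = 50
    positional_encoding: bool = True

    def __post_init__(self) -> None:
        if self.num_heads < 1 or self.key_dim < 1:
            raise ValueError("num_heads and key_dim must be >= 1")

    @property
    def ff_dim(self) -> int:
        return 2 * self.key_dim


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 120
    patience: int = 10
    min_delta: float = 1e-4
    batch_size: int | None = None  # None -> the model config's batch size
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class _Model:
    """Shared plumbing: parameter access, standardisation, batched inference."""

    def __init__(self) -> None:
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def params(self) -> list[Param]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def set_standardizer(self, mu: np.ndarray, sd: np.ndarray) -> None:
        self._mu = mu.astype(DTYPE)
        self._sd = np.maximum(sd, 1e-6).astype(DTYPE)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if self._mu is None:
            return X
        return (X - self._mu) / self._sd

    def forward(self, X, rng=None, train=False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits) -> None:
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(X[i : i + batch_size], rng=None, train=False)
            out.append(_softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


class _ConvBranch:
    """One per-channel convolutional stack mapping (B, window, 1) -> (B, 50).

    Used in shared-weights mode, where the 18 channels fold into the batch."""

    def __init__(self, cfg: ConvNetConfig, rng: np.random.Generator):
        self.layers: list = []
        c_in, length = 1, cfg.window
        for i, (c_out, k) in enumerate(cfg.conv_specs, start=1):
            self.layers.append(Conv1D(c_in, c_out, k, "selu", rng))
            length, c_in = length - k + 1, c_out
            if i in cfg.pool_after:
                self.layers.append(MaxPool1D(cfg.pool_size))
                length //= cfg.pool_size
        self.layers.append(Flatten())
        self.layers.append(Dense(length * c_in, cfg.dense_per_channel, "selu", rng))

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class _GroupedBranches:
    """All 18 separate-weight branches evaluated as grouped tensor ops.

    Maps (B, window, C) to (B, C * dense_per_channel) with an independent
    parameter set per channel — numerically identical to looping over 18
    :class:`_ConvBranch` instances but an order of magnitude faster.
    """

    def __init__(self, cfg: ConvNetConfig, rng: np.random.Generator):
        G = cfg.n_channels
        self.layers: list = []
        c_in, length = 1, cfg.window
        for i, (c_out, k) in enumerate(cfg.conv_specs, start=1):
            self.layers.append(GroupedConv1D(G, c_in, c_out, k, "selu", rng))
            length, c_in = length - k + 1, c_out
            if i in cfg.pool_after:
                self.layers.append(GroupedMaxPool1D(cfg.pool_size))
                length //= cfg.pool_size
        self._flat = length * c_in
        self.dense = GroupedDense(G, self._flat, cfg.dense_per_channel, "selu", rng)
        self.k = cfg.dense_per_channel

    def params(self):
        ps = [p for layer in self.layers for p in layer.params()]
        ps.extend(self.dense.params())
        return ps

    def forward(self, X):
        # (B, T, C) -> (C, B, T, 1)
        x = np.ascontiguousarray(X.transpose(2, 0, 1))[:, :, :, None]
        for layer in self.layers:
            x = layer.forward(x)
        G, B = x.shape[0], x.shape[1]
        feats = self.dense.forward(x.reshape(G, B, self._flat))  # (C, B, 50)
        self._conv_out_shape = x.shape
        return feats.transpose(1, 0, 2).reshape(B, G * self.k)

    def backward(self, dfeats):
        B = dfeats.shape[0]
        G = self._conv_out_shape[0]
        d = np.ascontiguousarray(dfeats.reshape(B, G, self.k).transpose(1, 0, 2))
        d = self.dense.backward(d).reshape(self._conv_out_shape)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class ConvNet1D(_Model):
    def __init__(self, config: ConvNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        if config.shared_branches:
            self.branch = _ConvBranch(config, rng)
        else:
            self.branch = _GroupedBranches(config, rng)
        d_concat = config.n_channels * config.dense_per_channel
        f1, f2 = config.fusion
        self.fuse1 = Dense(d_concat, f1, "selu", rng)
        self.drop1 = Dropout(config.dropout_rate)
        self.fuse2 = Dense(f1, f2, "selu", rng)
        self.drop2 = Dropout(config.dropout_rate)
        self.out = Dense(f2, config.n_classes, None, rng)

    def params(self):
        ps = list(self.branch.params())
        for layer in (self.fuse1, self.fuse2, self.out):
            ps.extend(layer.params())
        return ps

    def forward(self, X, rng=None, train=False):
        X = self._standardize(X)
        B, T, C = X.shape
        cfg = self.config
        if T != cfg.window or C != cfg.n_channels:
            raise ValueError(
                f"expected input (B, {cfg.window}, {cfg.n_channels}), got {X.shape}"
            )
        if cfg.shared_branches:
            folded = np.ascontiguousarray(X.transpose(0, 2, 1)).reshape(B * C, T, 1)
            feats = self.branch.forward(folded).reshape(B, C * cfg.dense_per_channel)
        else:
            feats = self.branch.forward(X)
        h = self.drop1.forward(self.fuse1.forward(feats), rng, train)
        h = self.drop2.forward(self.fuse2.forward(h), rng, train)
        return self.out.forward(h)

    def backward(self, dlogits):
        d = self.out.backward(dlogits)
        d = self.fuse2.backward(self.drop2.backward(d))
        d = self.fuse1.backward(self.drop1.backward(d))
        cfg = self.config
        if cfg.shared_branches:
            B = d.shape[0]
            self.branch.backward(d.reshape(B * cfg.n_channels, cfg.dense_per_channel))
        else:
            self.branch.backward(d)


class _EncoderBlock:
    """Pre-norm transformer encoder block with residual connections."""

    def __init__(self, d_model: int, heads: int, key_dim: int, ff_dim: int,
                 dropout: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.mha = MultiHeadSelfAttention(d_model, heads, key_dim, dropout, rng)
        self.drop = Dropout(dropout)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, ff_dim, "selu", rng)
        self.ffdrop = Dropout(dropout)
        self.ff2 = Dense(ff_dim, d_model, None, rng)

    def params(self):
        ps = []
        for layer in (self.ln1, self.mha, self.ln2, self.ff1, self.ff2):
            ps.extend(layer.params())
        return ps

    def forward(self, x, rng=None, train=False):
        h = x + self.drop.forward(self.mha.forward(self.ln1.forward(x), rng, train), rng, train)
        return h + self.ff2.forward(self.ffdrop.forward(self.ff1.forward(self.ln2.forward(h)),
                                                        rng, train))

    def backward(self, d):
        dh = d + self.ln2.backward(
            self.ff1.backward(self.ffdrop.backward(self.ff2.backward(d)))
        )
        return dh + self.ln1.backward(self.mha.backward(self.drop.backward(dh)))


def _sensor_positional_encoding(n_tokens: int, d: int) -> np.ndarray:
    """Fixed sinusoidal encoding over the sensor index."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return pe.astype(DTYPE)


class TimeSpatialTransformer(_Model):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        cfg = config
        self.time_blocks = [
            _EncoderBlock(1, cfg.num_heads, cfg.key_dim, cfg.ff_dim, cfg.dropout_rate, rng)
            for _ in range(cfg.num_blocks)
        ]
        self.fusion = Dense(cfg.window, cfg.d_embed, "selu", rng)
        self.pe = _sensor_positional_encoding(cfg.n_channels, cfg.d_embed)
        self.spatial_blocks = [
            _EncoderBlock(cfg.d_embed, cfg.num_heads, cfg.key_dim, cfg.ff_dim,
                          cfg.dropout_rate, rng)
            for _ in range(cfg.num_blocks)
        ]
        self.head1 = Dense(cfg.d_embed, cfg.head_hidden, "selu", rng)
        self.head_drop = Dropout(cfg.dropout_rate)
        self.head2 = Dense(cfg.head_hidden, cfg.n_classes, None, rng)

    def params(self):
        ps = []
        for block in self.time_blocks + self.spatial_blocks:
            ps.extend(block.params())
        for layer in (self.fusion, self.head1, self.head2):
            ps.extend(layer.params())
        return ps

    @property
    def spatial_tokens(self) -> int:
        return self.config.n_channels

    def forward(self, X, rng=None, train=False):
        X = self._standardize(X)
        B, T, C = X.shape
        cfg = self.config
        if T != cfg.window or C != cfg.n_channels:
            raise ValueError(
                f"expected input (B, {cfg.window}, {cfg.n_channels}), got {X.shape}"
            )
        x = X.transpose(0, 2, 1).reshape(B * C, T, 1)
        for block in self.time_blocks:
            x = block.forward(x, rng, train)
        emb = self.fusion.forward(x.reshape(B * C, T))
        tokens = emb.reshape(B, C, cfg.d_embed)
        if cfg.positional_encoding:
            tokens = tokens + self.pe
        for block in self.spatial_blocks:
            tokens = block.forward(tokens, rng, train)
        pooled = tokens.mean(axis=1)
        h = self.head_drop.forward(self.head1.forward(pooled), rng, train)
        return self.head2.forward(h)

    def backward(self, dlogits):
        cfg = self.config
        d = self.head1.backward(self.head_drop.backward(self.head2.backward(dlogits)))
        B = d.shape[0]
        C = cfg.n_channels
        dtokens = np.broadcast_to(d[:, None, :] / C, (B, C, cfg.d_embed)).astype(DTYPE).copy()
        for block in reversed(self.spatial_blocks):
            dtokens = block.backward(dtokens)
        demb = self.fusion.backward(dtokens.reshape(B * C, cfg.d_embed))
        dx = demb.reshape(B * C, cfg.window, 1)
        for block in reversed(self.time_blocks):
            dx = block.backward(dx)


def build_convnet(config: ConvNetConfig | None = None,
                  rng: np.random.Generator | None = None) -> ConvNet1D:
    return ConvNet1D(config or ConvNetConfig(), rng)


def build_time_spatial_transformer(config: TransformerConfig | None = None,
                                   rng: np.random.Generator | None = None) -> TimeSpatialTransformer:
    return TimeSpatialTransformer(config or TransformerConfig(), rng)


def build_model(spec, n_channels: int | None = None,
                rng: np.random.Generator | None = None) -> _Model:
    """Build a classifier from a config object or the name 'convnet'/'transformer'.

    ``n_channels`` overrides the config's channel count (sensor ablation)."""
    from dataclasses import replace

    if isinstance(spec, str):
        spec = {"convnet": ConvNetConfig, "transformer": TransformerConfig}[spec]()
    if n_channels is not None and spec.n_channels != n_channels:
        spec = replace(spec, n_channels=n_channels)
    if isinstance(spec, ConvNetConfig):
        return ConvNet1D(spec, rng)
    if isinstance(spec, TransformerConfig):
        return TimeSpatialTransformer(spec, rng)
    raise TypeError(f"unknown model spec {spec!r}")


def _eval_loss_acc(model: _Model, X, y, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i : i + batch_size], rng=None, train=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    model: _Model,
    train_batch: SegmentBatch,
    val_batch: SegmentBatch,
    config: TrainConfig | None = None,
) -> list[dict]:
    """Fit the model; returns the per-epoch history (loss, val_loss, val_acc).

    Early stopping monitors validation loss and restores the best-epoch
    weights.  Raises :class:`TrainingDiverged` on a non-finite loss.  Fully
    deterministic under ``config.seed``.
    """
    cfg = config or TrainConfig()
    if len(train_batch) == 0 or len(val_batch) == 0:
        raise ValueError("train and validation batches must be non-empty")
    overlap = train_batch.subject_ids & val_batch.subject_ids
    if overlap:
        raise AssertionError(f"train/validation subjects overlap: {sorted(overlap)}")
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(train_batch.segments, dtype=DTYPE)
    y = train_batch.labels
    Xv = np.asarray(val_batch.segments, dtype=DTYPE)
    yv = val_batch.labels
    if cfg.standardize:
        model.set_standardizer(X.mean(axis=(0, 1)), X.std(axis=(0, 1)))
    batch_size = cfg.batch_size or model.config.batch_size
    opt = Nadam(model.params(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    history: list[dict] = []
    best_loss, best_state, wait = np.inf, model.state(), 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for i in range(0, len(X), batch_size):
            idx = order[i : i + batch_size]
            logits = model.forward(X[idx], rng=rng, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        val_loss, val_acc = _eval_loss_acc(model, Xv, yv, batch_size)
        history.append(
            {"epoch": epoch, "loss": epoch_loss / len(X), "val_loss": val_loss,
             "val_acc": val_acc}
        )
        if val_loss < best_loss - cfg.min_delta:
            best_loss, best_state, wait = val_loss, model.state(), 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.load_state(best_state)
    return history


def predict_segments(model: _Model, batch: SegmentBatch,
                     batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Argmax class per segment plus the full probability matrix."""
    probs = model.predict_proba(np.asarray(batch.segments, dtype=DTYPE), batch_size)
    return probs.argmax(axis=1), probs
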