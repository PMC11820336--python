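"""1D convolutional three-class spectral classifier (pure numpy).

A reflectance curve over 450-700 nm (126 points) is downsampled by two
Conv1d+ReLU+maxpool blocks and two linear layers into three logits, one per
group {0: "2D", 1: "Real", 2: "3D"}; softmax turns them into class
probabilities and argmax into the group number. Training minimizes
cross-entropy with the Adadelta optimizer under the reference schedule:
batch 2048, 200 epochs, a learning-rate profile starting at 4e-4 and halving
every 25 epochs, a checkpoint saved on every new minimum validation loss, and
checkpointing frozen once neither loss minimum has improved for 10
consecutive epochs (training still runs to completion for the full loss
curve).

Note on the learning-rate scale: Adadelta's accumulator-ratio updates are
nearly scale-free with a natural unit step; the nominal 4e-4 figure is kept as
the schedule's bookkeeping value, and the optimizer consumes the *relative*
decay profile lr(epoch)/lr(0) by default (see docs/methods.md). Set
``TrainConfig.lr_absolute=True`` to multiply raw updates by lr(epoch) instead.
"""

from __future__ import annotations


import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "SpectralCNN",
    "TrainedModel",
    "build_model",
    "train_model",
    "predict_proba",
    "predict_sample",
    "lr_at_epoch",
]

logger = logging.getLogger(__name__)

N_CLASSES = 3


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture: conv blocks (in_ch, out_ch, kernel) each followed by
    ReLU and maxpool-2, then linear hidden layer, then the 3-way output."""

    input_length: int = 126
    conv_blocks: tuple = ((1, 16, 7), (16, 32, 5))
    hidden: int = 64
    classes: int = N_CLASSES

    def layer_lengths(self) -> list[int]:
        """Sequence lengths after each conv+pool block; validates chaining."""
        lengths = [self.input_length]
        ch = 1
        for i, (cin, cout, k) in enumerate(self.conv_blocks):
            if cin != ch:
                raise ValueError(
                    f"conv block {i}: expects in-channels {cin} but receives {ch}"
                )
            L = lengths[-1] - k + 1
            if L < 2:
                raise ValueError(
                    f"conv block {i}: kernel {k} leaves length {L} < 2 "
                    f"from input length {lengths[-1]}"
                )
            lengths.append(L // 2)  # maxpool-2 (odd tail dropped)
            ch = cout
        return lengths

    @property
    def flat_features(self) -> int:
        return self.conv_blocks[-1][1] * self.layer_lengths()[-1]


@dataclass
class TrainConfig:
    """The reference training protocol (desk-scale runs shrink `epochs`)."""

    batch_size: int = 2048
    epochs: int = 200
    initial_lr: float = 0.0004
    lr_half_period: int = 25
    rho: float = 0.9
    eps: float = 1e-6
    patience: int = 10
    seed: int = 0
    lr_absolute: bool = False

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.lr_half_period) < 1:
            raise ValueError("batch_size, epochs and lr_half_period must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.patience < self.epochs:
            raise ValueError(
                f"patience must lie in (0, epochs), got {self.patience} vs "
                f"{self.epochs} epochs"
            )


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Scheduled learning rate: initial_lr halved every lr_half_period epochs."""
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_half_period)


def _conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """X (N,C,L), W (O,C,K) -> Y (N,O,L-K+1) via im2col + BLAS matmul."""
    O, C, K = W.shape
    win = sliding_window_view(X, K, axis=2)          # (N, C, L', K) view
    patches = np.ascontiguousarray(win.transpose(0, 2, 1, 3))  # (N, L', C, K)
    N, Lp = patches.shape[:2]
    flat = patches.reshape(N * Lp, C * K)
    Y = (flat @ W.reshape(O, C * K).T).reshape(N, Lp, O).transpose(0, 2, 1) + \
        b[None, :, None]
    return Y, flat


def _conv1d_backward(dY: np.ndarray, flat: np.ndarray, W: np.ndarray, in_len: int):
    O, C, K = W.shape
    N, _, Lp = dY.shape
    dYmat = np.ascontiguousarray(dY.transpose(0, 2, 1)).reshape(N * Lp, O)
    dW = (dYmat.T @ flat).reshape(O, C, K)
    db = dY.sum(axis=(0, 2))
    dpatch = (dYmat @ W.reshape(O, C * K)).reshape(N, Lp, C, K)
    dX = np.zeros((N, C, in_len), dtype=dY.dtype)
    for k in range(K):  # scatter-add each kernel tap (K is small)
        dX[:, :, k : k + Lp] += dpatch[:, :, :, k].transpose(0, 2, 1)
    return dX, dW, db


def _maxpool2(X: np.ndarray):
    L2 = X.shape[2] // 2
    pairs = X[:, :, : 2 * L2].reshape(X.shape[0], X.shape[1], L2, 2)
    idx = pairs.argmax(axis=3)
    return pairs.max(axis=3), (idx, X.shape[2])


def _maxpool2_backward(dY: np.ndarray, cache):
    idx, L = cache
    n, c, L2 = dY.shape
    pairs = np.zeros((n, c, L2, 2), dtype=dY.dtype)
    np.put_along_axis(pairs, idx[..., None], dY[..., None], axis=3)
    dX = np.zeros((n, c, L), dtype=dY.dtype)
    dX[:, :, : 2 * L2] = pairs.reshape(n, c, 2 * L2)
    return dX


class SpectralCNN:
    """Weights + forward/backward passes for the ClassifierSpec architecture.

    float32 by default (halves single-core training time); pass
    ``dtype=np.float64`` for numerical checks such as finite-difference
    gradient verification.
    """

    def __init__(self, spec: ClassifierSpec, seed: int = 0, dtype=np.float32):
        spec.layer_lengths()  # validates chaining
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (cin, cout, k) in enumerate(spec.conv_blocks):
            fan_in = cin * k
            self.params[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (cout, cin, k))
            self.params[f"bc{i}"] = np.zeros(cout)
        flat = spec.flat_features
        self.params["W_h"] = rng.normal(0, np.sqrt(2.0 / flat), (flat, spec.hidden))
        self.params["b_h"] = np.zeros(spec.hidden)
        self.params["W_o"] = rng.normal(0, np.sqrt(2.0 / spec.hidden),
                                        (spec.hidden, spec.classes))
        self.params["b_o"] = np.zeros(spec.classes)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    def forward(self, X: np.ndarray, need_cache: bool = False):
        X = np.asarray(X, self.dtype)
        if X.ndim != 2 or X.shape[1] != self.spec.input_length:
            raise ValueError(
                f"input must be (n, {self.spec.input_length}), got {X.shape}"
            )
        a = X[:, None, :]  # (N, 1, L)
        cache = {"input": a}
        for i in range(len(self.spec.conv_blocks)):
            W, b = self.params[f"Wc{i}"], self.params[f"bc{i}"]
            z, win = _conv1d_forward(a, W, b)
            r = np.maximum(z, 0.0)
            p, pool_cache = _maxpool2(r)
            cache[f"conv{i}"] = (a.shape[2], win, z, pool_cache)
            a = p
        n = a.shape[0]
        flat = a.reshape(n, -1)
        h_z = flat @ self.params["W_h"] + self.params["b_h"]
        h = np.maximum(h_z, 0.0)
        logits = h @ self.params["W_o"] + self.params["b_o"]
        cache.update(flat=flat, h_z=h_z, h=h, conv_out_shape=a.shape)
        return (logits, cache) if need_cache else logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        grads["W_o"] = cache["h"].T @ dlogits
        grads["b_o"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W_o"].T
        dh_z = dh * (cache["h_z"] > 0)
        grads["W_h"] = cache["flat"].T @ dh_z
        grads["b_h"] = dh_z.sum(axis=0)
        dflat = dh_z @ self.params["W_h"].T
        da = dflat.reshape(cache["conv_out_shape"])
        for i in reversed(range(len(self.spec.conv_blocks))):
            in_len, win, z, pool_cache = cache[f"conv{i}"]
            dr = _maxpool2_backward(da, pool_cache)
            dz = dr * (z > 0)
            da, dW, db = _conv1d_backward(dz, win, self.params[f"Wc{i}"], in_len)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].astype(self.dtype)


def build_model(spec: ClassifierSpec = ClassifierSpec(), seed: int = 0,
                dtype=np.float32) -> SpectralCNN:
    """Untrained model with reproducible He initialization."""
    return SpectralCNN(spec, seed=seed, dtype=dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adadelta:
    """Accumulator-ratio adaptive optimizer (per-parameter RMS step sizes)."""

    def __init__(self, params: dict[str, np.ndarray], rho: float = 0.9,
                 eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self.Eg = {k: np.zeros_like(v) for k, v in params.items()}
        self.Edx = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             scale: float = 1.0) -> None:
        for k, g in grads.items():
            self.Eg[k] = self.rho * self.Eg[k] + (1 - self.rho) * g * g
            dx = np.sqrt((self.Edx[k] + self.eps) / (self.Eg[k] + self.eps)) * g
            self.Edx[k] = self.rho * self.Edx[k] + (1 - self.rho) * dx * dx
            params[k] -= scale * dx


@dataclass
class TrainedModel:
    model: SpectralCNN
    spec: ClassifierSpec
    cfg: TrainConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    checkpoint: Optional[dict] = None

    def restore_best(self) -> None:
        if self.checkpoint is not None:
            self.model.load_params(self.checkpoint)


def _epoch_loss(model: SpectralCNN, X: np.ndarray, y: np.ndarray,
                batch: int) -> float:
    total, n = 0.0, X.shape[0]
    for i in range(0, n, batch):
        logits = model.forward(X[i : i + batch])
        loss, _ = cross_entropy(logits, y[i : i + batch])
        total += loss * logits.shape[0]
    return total / n


def train_model(
    model: SpectralCNN,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Mini-batch Adadelta training with the checkpoint/stale-epoch rule.

    A checkpoint is taken whenever the validation loss reaches a new minimum.
    Once neither the training-loss minimum nor the validation-loss minimum
    has improved for `cfg.patience` consecutive epochs (and the epoch index
    exceeds `cfg.patience`), further checkpoints are suppressed as likely
    overfitting; training still runs all epochs to complete the loss curves.
    """
    X, y = np.asarray(train[0], float), np.asarray(train[1], np.intp)
    Xv, yv = np.asarray(val[0], float), np.asarray(val[1], np.intp)
    if X.shape[0] == 0 or Xv.shape[0] == 0:
        raise ValueError("training and validation sets must be nonempty")
    if not (set(np.unique(y)) <= {0, 1, 2} and set(np.unique(yv)) <= {0, 1, 2}):
        raise ValueError("labels must lie in {0, 1, 2}")
    batch = cfg.batch_size
    if batch > X.shape[0]:
        warnings.warn(
            f"batch size {batch} exceeds training set size {X.shape[0]}; "
            f"clamping to full-batch"
        )
        batch = X.shape[0]

    rng = np.random.default_rng(cfg.seed)
    opt = Adadelta(model.params, rho=cfg.rho, eps=cfg.eps)
    result = TrainedModel(model=model, spec=model.spec, cfg=cfg,
                          history={"train_loss": [], "val_loss": [], "lr": []})
    best_train = np.inf
    stale = 0
    checkpoint_frozen = False

    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        scale = lr if cfg.lr_absolute else lr / cfg.initial_lr
        order = rng.permutation(X.shape[0])
        batch_losses, batch_sizes = [], []
        for i in range(0, X.shape[0], batch):
            sel = order[i : i + batch]
            logits, cache = model.forward(X[sel], need_cache=True)
            loss, dlogits = cross_entropy(logits, y[sel])
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads, scale=scale)
            batch_losses.append(loss)
            batch_sizes.append(sel.size)

        # training loss: weighted mean of the minibatch losses of this epoch
        tr_loss = float(np.average(batch_losses, weights=batch_sizes))
        va_loss = _epoch_loss(model, Xv, yv, batch)
        result.history["train_loss"].append(tr_loss)
        result.history["val_loss"].append(va_loss)
        result.history["lr"].append(lr)

        improved = False
        if tr_loss < best_train:
            best_train = tr_loss
            improved = True
        if va_loss < result.best_val_loss:
            result.best_val_loss = va_loss
            improved = True
            if not checkpoint_frozen:
                result.checkpoint = model.copy_params()
                result.best_epoch = epoch
        stale = 0 if improved else stale + 1
        if stale >= cfg.patience and epoch > cfg.patience and not checkpoint_frozen:
            checkpoint_frozen = True
            logger.info(
                "epoch %d: no loss improvement for %d epochs; checkpointing "
                "frozen (training continues)", epoch, cfg.patience,
            )
        logger.debug("epoch %d lr %.2e train %.4f val %.4f",
                     epoch, lr, tr_loss, va_loss)

    if result.checkpoint is None:  # val loss never improved at all
        result.checkpoint = model.copy_params()
        result.best_epoch = 0
    result.restore_best()
    return result


def predict_proba(trained: TrainedModel | SpectralCNN, X: np.ndarray) -> np.ndarray:
    """(n, 3) class probabilities (softmax over logits); rows sum to 1."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    return softmax(model.forward(np.atleast_2d(np.asarray(X, float))))


def predict_sample(
    trained: TrainedModel | SpectralCNN, sample: np.ndarray
) -> tuple[int, np.ndarray]:
    """Per-row argmax tally over a compressed sample.

    Returns (majority label, per-class proportions); exact ties break to the
    lowest class index.
    """
    proba = predict_proba(trained, sample)
    labels = proba.argmax(axis=1)
    counts = np.bincount(labels, minlength=N_CLASSES).astype(float)
    proportions = counts / counts.sum()
    return int(counts.argmax()), proportions
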