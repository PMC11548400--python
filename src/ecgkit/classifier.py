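"""Lightweight 1D CNN beat classifier (MLCNN).

Architecture: up to four ``Conv1D(kᵢ filters, fᵢ kernel, ReLU) → MaxPool``
blocks, a single dropout layer, then ``Flatten → Dense(n₁, ReLU, L2) →
Dense(n₂, softmax)``.  Trained with Adam on categorical cross-entropy.

The network is implemented directly on numpy (im2col windows + BLAS matrix
products for the convolutions, vectorised pooling), which keeps the whole
training loop bit-deterministic for a fixed seed — every acceptance run and
benchmark rerun reproduces exactly.  Defaults are conventional
lightweight-CNN settings: filters (32, 64, 128, 256), kernels (7, 5, 5, 3),
pool 2, dropout 0.3, 64 dense units, L2 1e-4, Adam lr 1e-3, batch 128.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .metrics import ClassificationReport, classification_report, confusion_matrix
from .synth import BEAT_CLASSES, DatasetBundle

_DT = np.float32


@dataclass
class ModelConfig:
    conv_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [(32, 7), (64, 5), (128, 5), (256, 3)])
    pool_size: int = 2
    dropout_rate: float = 0.3
    dense_units: int = 64
    n_classes: int = len(BEAT_CLASSES)
    l2_coefficient: float = 1e-4

    def __post_init__(self) -> None:
        if not 1 <= len(self.conv_blocks) <= 4:
            raise ValueError("between 1 and 4 conv blocks are supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def min_input_length(self) -> int:
        """Smallest input that survives every conv (valid) and pool halving."""
        n = 1
        for _, f in reversed(self.conv_blocks):
            n = n * self.pool_size
            n = n + f - 1
        return n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [list(b) for b in self.conv_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_blocks"] = [tuple(b) for b in d["conv_blocks"]]
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# vectorised layer primitives

def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) sliding windows, C fastest within a tap."""
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, Lo, C, k)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2])


def _conv_forward(x, W, b):
    """Valid correlation. x: (B, L, Cin); W: (k, Cin, Cout); returns y, cols."""
    k, cin, cout = W.shape
    cols = _windows(x, k)                              # (B, Lo, k*Cin)
    y = cols.reshape(-1, k * cin) @ W.reshape(k * cin, cout) + b
    return y.reshape(x.shape[0], -1, cout), cols


def _conv_backward(dy, cols, W, input_len):
    k, cin, cout = W.shape
    B, lo, _ = dy.shape
    dW = (cols.reshape(-1, k * cin).T @ dy.reshape(-1, cout)).reshape(k, cin, cout)
    db = dy.sum(axis=(0, 1))
    # dx is the full correlation of dy with the flipped kernel
    dyp = np.zeros((B, lo + 2 * (k - 1), cout), dtype=dy.dtype)
    dyp[:, k - 1:k - 1 + lo] = dy
    cols_d = _windows(dyp, k)                          # (B, input_len, k*Cout)
    Wf = W[::-1].transpose(0, 2, 1).reshape(k * cout, cin)  # [j,co,ci] = W[k-1-j,ci,co]
    dx = cols_d.reshape(-1, k * cout) @ Wf
    return dx.reshape(B, input_len, cin), dW, db


def _pool_forward(x, size):
    B, L, C = x.shape
    lp = L // size
    xr = x[:, :lp * size].reshape(B, lp, size, C)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (idx, L)


def _pool_backward(dy, cache, size):
    idx, L = cache
    B, lp, C = dy.shape
    dxr = np.zeros((B, lp, size, C), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros((B, L, C), dtype=dy.dtype)
    dx[:, :lp * size] = dxr.reshape(B, lp * size, C)
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLCNN:
    """The built network: parameter state plus forward/backward passes."""

    def __init__(self, config: ModelConfig, input_length: int, seed: int = 0):
        if input_length < config.min_input_length():
            raise ValueError(
                f"input length {input_length} too short; this architecture "
                f"needs at least {config.min_input_length()} samples"
            )
        self.config = config
        self.input_length = int(input_length)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        self.params: dict[str, np.ndarray] = {}
        cin, length = 1, input_length
        for i, (filters, kernel) in enumerate(config.conv_blocks):
            fan_in = kernel * cin
            self.params[f"W{i}"] = (rng.standard_normal((kernel, cin, filters))
                                    * np.sqrt(2.0 / fan_in)).astype(_DT)
            self.params[f"b{i}"] = np.zeros(filters, dtype=_DT)
            length = (length - kernel + 1) // config.pool_size
            cin = filters
        self.flat_dim = length * cin
        self.params["Wd1"] = (rng.standard_normal((self.flat_dim, config.dense_units))
                              * np.sqrt(2.0 / self.flat_dim)).astype(_DT)
        self.params["bd1"] = np.zeros(config.dense_units, dtype=_DT)
        self.params["Wd2"] = (rng.standard_normal((config.dense_units, config.n_classes))
                              * np.sqrt(2.0 / config.dense_units)).astype(_DT)
        self.params["bd2"] = np.zeros(config.n_classes, dtype=_DT)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """x: (B, input_length) -> class probabilities (B, n_classes) + cache."""
        cfg = self.config
        h = np.asarray(x, dtype=_DT)[:, :, None]
        cache: dict = {"inputs": []}
        for i in range(len(cfg.conv_blocks)):
            in_len = h.shape[1]
            z, cols = _conv_forward(h, self.params[f"W{i}"], self.params[f"b{i}"])
            a = np.maximum(z, 0)
            p, pc = _pool_forward(a, cfg.pool_size)
            cache["inputs"].append((in_len, cols, z, pc))
            h = p
        if training and cfg.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = (rng.random(h.shape) >= cfg.dropout_rate).astype(_DT)
            h = h * keep / _DT(1.0 - cfg.dropout_rate)
            cache["drop"] = keep
        cache["pooled_shape"] = h.shape
        flat = h.reshape(h.shape[0], -1)
        z1 = flat @ self.params["Wd1"] + self.params["bd1"]
        a1 = np.maximum(z1, 0)
        logits = a1 @ self.params["Wd2"] + self.params["bd2"]
        probs = _softmax(logits.astype(np.float64)).astype(_DT)
        cache.update(flat=flat, z1=z1, a1=a1, probs=probs)
        return probs, cache

    def backward(self, cache, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy (+ L2 on the first dense weights)."""
        cfg = self.config
        B = y_onehot.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot.astype(_DT)) / _DT(B)
        grads["Wd2"] = cache["a1"].T @ dlogits
        grads["bd2"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["Wd2"].T
        dz1 = da1 * (cache["z1"] > 0)
        grads["Wd1"] = cache["flat"].T @ dz1 + \
            _DT(2.0 * cfg.l2_coefficient) * self.params["Wd1"]
        grads["bd1"] = dz1.sum(axis=0)
        dh = (dz1 @ self.params["Wd1"].T).reshape(cache["pooled_shape"])
        if "drop" in cache:
            dh = dh * cache["drop"] / _DT(1.0 - cfg.dropout_rate)
        for i in reversed(range(len(cfg.conv_blocks))):
            in_len, cols, z, pc = cache["inputs"][i]
            da = _pool_backward(dh, pc, cfg.pool_size)
            dz = da * (z > 0)
            dh, grads[f"W{i}"], grads[f"b{i}"] = _conv_backward(
                dz, cols, self.params[f"W{i}"], in_len)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(x), batch_size):
            out.append(self.forward(x[s:s + batch_size])[0])
        return np.concatenate(out, axis=0)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(x).argmax(axis=1)
        return np.array(BEAT_CLASSES)[idx]

    # -- persistence --------------------------------------------------------

    def save(self, path: "str | Path") -> None:
        import json

        meta = json.dumps({"config": self.config.to_dict(),
                           "input_length": self.input_length, "seed": self.seed})
        np.savez(Path(path), __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path: "str | Path") -> "MLCNN":
        import json

        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            model = cls(ModelConfig.from_dict(meta["config"]),
                        meta["input_length"], meta["seed"])
            for k in model.params:
                model.params[k] = z[k]
        return model


def build_mlcnn(config: ModelConfig, input_length: int, seed: int = 0) -> MLCNN:
    """Construct the network with seeded (deterministic) He-normal init."""
    return MLCNN(config, input_length, seed)


@dataclass
class TrainedModel:
    model: MLCNN
    train_config: TrainConfig
    history: list[dict]          # per-epoch train/val loss and accuracy

    def evaluate(self, test: DatasetBundle) -> ClassificationReport:
        return evaluate(self, test)


def _labels_to_onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(BEAT_CLASSES)}
    y = np.array([index[lab] for lab in labels])
    if y.max() >= n_classes:
        raise ValueError("label outside the model's class range")
    onehot = np.zeros((len(y), n_classes), dtype=_DT)
    onehot[np.arange(len(y)), y] = 1
    return onehot


def _ce_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs[onehot.astype(bool)], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def train(model: MLCNN, train_set: DatasetBundle,
          val_set: DatasetBundle | None = None,
          tc: TrainConfig | None = None) -> TrainedModel:
    """Adam training on categorical cross-entropy; fully seeded.

    Per-epoch history records the running training loss/accuracy (over the
    shuffled mini-batches of that epoch) and, when a validation set is given,
    the post-epoch validation loss/accuracy.
    """
    tc = tc or TrainConfig()
    if len(train_set.labels) == 0:
        raise ValueError("training set is empty")
    if train_set.segment_length != model.input_length:
        raise ValueError(
            f"segment length {train_set.segment_length} does not match "
            f"model input length {model.input_length}"
        )
    x = np.asarray(train_set.segments, dtype=_DT)
    y = _labels_to_onehot(train_set.labels, model.config.n_classes)
    xv = yv = None
    if val_set is not None and len(val_set.labels):
        xv = np.asarray(val_set.segments, dtype=_DT)
        yv = _labels_to_onehot(val_set.labels, model.config.n_classes)

    rng = np.random.default_rng(tc.seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history: list[dict] = []

    for epoch in range(tc.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for s in range(0, len(x), tc.batch_size):
            idx = order[s:s + tc.batch_size]
            xb, yb = x[idx], y[idx]
            probs, cache = model.forward(xb, training=True, rng=rng)
            losses.append(_ce_loss(probs, yb) * len(idx))
            correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            grads = model.backward(cache, yb)
            t += 1
            lr_t = tc.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
            for k, g in grads.items():
                g = g.astype(_DT)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                model.params[k] -= (_DT(lr_t) * m[k]
                                    / (np.sqrt(v[k]) + _DT(eps))).astype(_DT)
        row = {"epoch": epoch + 1,
               "train_loss": float(np.sum(losses) / len(x)),
               "train_acc": correct / len(x)}
        if xv is not None:
            pv = model.predict_proba(xv)
            row["val_loss"] = _ce_loss(pv, yv)
            row["val_acc"] = float((pv.argmax(1) == yv.argmax(1)).mean())
        history.append(row)
    return TrainedModel(model, tc, history)


def evaluate(trained: "TrainedModel | MLCNN",
             test: DatasetBundle) -> ClassificationReport:
    """Predict by softmax argmax and build the full classification report."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if len(test.labels) == 0:
        raise ValueError("test set is empty")
    if test.segment_length != model.input_length:
        raise ValueError(
            f"segment length {test.segment_length} does not match "
            f"model input length {model.input_length}"
        )
    pred = model.predict_labels(np.asarray(test.segments, dtype=_DT))
    cm = confusion_matrix(test.labels, pred)
    return classification_report(cm)


def history_to_csv(history: list[dict], path: "str | Path") -> None:
    import csv

    cols = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
    with Path(path).open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in history:
            w.writerow({c: row.get(c, "") for c in cols})
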