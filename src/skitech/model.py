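"""The unified CNN-LSTM technique classifier.

Architecture (time axis, valid padding, all channels fused in one step):

    Conv1D(64, k=20) -> ReLU -> Conv1D(64, k=10) -> ReLU -> MaxPool(4)
    -> LSTM(300) -> Dropout(0.2) -> LSTM(200) -> Dropout(0.2)
    -> Dense(8) -> softmax

The convolutions extract local interactions among the gyroscope channels of
a cycle, max-pooling makes the features robust to amplitude/speed scale, and
the stacked LSTMs capture the temporal ordering of the pooled features; the
final hidden state feeds the softmax over the eight technique classes.
Training uses categorical cross-entropy and Adam for a fixed 12 epochs with
batch size 40 (no early stopping).  Estimator-style API: build the
classifier from a :class:`ModelSpec`, ``fit`` a cycle set, get back a
:class:`TrainedModel` results object that predicts and summarizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .io import TECHNIQUES, ValidationError
from .segmentation import CycleSet

__all__ = ["ModelSpec", "CNNLSTMClassifier", "TrainedModel", "conv_output_length"]

CLASS_ORDER = tuple(sorted(TECHNIQUES))  # (1..8)


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the CNN-LSTM classifier (defaults are the shipped
    configuration: conv 64x20 + 64x10, pool 4, LSTM 300+200, dropout 0.2,
    12 epochs, batch 40)."""

    conv_filters: tuple[int, int] = (64, 64)
    conv_kernels: tuple[int, int] = (20, 10)
    pool_size: int = 4
    lstm_units: tuple[int, int] = (300, 200)
    dropout_p: float = 0.2
    n_classes: int = 8
    epochs: int = 12
    batch_size: int = 40
    learning_rate: float = 1e-3
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        counts = (*self.conv_filters, *self.conv_kernels, self.pool_size,
                  *self.lstm_units, self.n_classes, self.epochs, self.batch_size)
        if any(c < 1 for c in counts):
            raise ValidationError("all architecture counts must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValidationError("dropout_p must be in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("conv_filters", "conv_kernels", "lstm_units"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelSpec(**d)


def conv_output_length(L: int, kernels, pool: int) -> int:
    """Time length after the valid convolutions and the pooling layer."""
    for k in kernels:
        L = L - k + 1
        if L < 1:
            raise ValidationError(f"input too short for kernel {k}")
    return L // pool


def build_network(spec: ModelSpec, input_shape: tuple[int, int],
                  rng: np.random.Generator) -> nn.Sequential:
    """Instantiate the layer stack for cycles of shape ``(L, C)``."""
    L, C = input_shape
    if C < 1:
        raise ValidationError("need at least one channel")
    pooled = conv_output_length(L, spec.conv_kernels, spec.pool_size)
    if pooled < 1:
        raise ValidationError(f"cycle length {L} too short for the conv/pool stack")
    f1, f2 = spec.conv_filters
    k1, k2 = spec.conv_kernels
    u1, u2 = spec.lstm_units
    return nn.Sequential([
        nn.Conv1D(C, f1, k1, rng),
        nn.ReLU(),
        nn.Conv1D(f1, f2, k2, rng),
        nn.ReLU(),
        nn.MaxPool1D(spec.pool_size),
        nn.LSTM(f2, u1, rng, return_sequences=True),
        nn.Dropout(spec.dropout_p, rng),
        nn.LSTM(u1, u2, rng, return_sequences=False),
        nn.Dropout(spec.dropout_p, rng),
        nn.Dense(u2, spec.n_classes, rng),
    ])


def _as_xy(data, labels=None):
    if isinstance(data, CycleSet):
        return data.cycles, data.labels, data.channels
    x = np.asarray(data, dtype=np.float32)
    y = None if labels is None else np.asarray(labels)
    return x, y, None


class CNNLSTMClassifier:
    """Estimator wrapper: ``CNNLSTMClassifier(spec).fit(cycles)``."""

    def __init__(self, spec: ModelSpec = ModelSpec()):
        self.spec = spec

    def fit(self, train: CycleSet, seed: int | None = None,
            verbose: bool = False) -> "TrainedModel":
        """Train on a cycle set; returns the results object.

        Deterministic for a fixed seed: one generator stream drives weight
        initialization, epoch shuffling and dropout masks in a fixed order.
        """
        spec = self.spec
        x, y, channels = _as_xy(train)
        if x.shape[0] == 0:
            raise ValidationError("cannot train on an empty cycle set")
        seed = spec.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        present = set(np.unique(y).tolist())
        if present - set(CLASS_ORDER):
            raise ValidationError(f"labels outside technique codes: {sorted(present - set(CLASS_ORDER))}")
        if set(CLASS_ORDER) - present:
            import warnings
            warnings.warn(f"training labels missing classes {sorted(set(CLASS_ORDER) - present)}")
        net = build_network(spec, x.shape[1:], rng)
        y_idx = np.searchsorted(CLASS_ORDER, y)
        opt = nn.Adam(net.params(), lr=spec.learning_rate, clip_norm=spec.grad_clip)
        n = x.shape[0]
        log = []
        for epoch in range(spec.epochs):
            order = rng.permutation(n)
            total_loss, correct = 0.0, 0
            for start in range(0, n, spec.batch_size):
                idx = order[start:start + spec.batch_size]
                xb, yb = x[idx], y_idx[idx]
                logits = net.forward(xb, train=True)
                loss, dlogits, probs = nn.softmax_cross_entropy(logits, yb)
                net.backward(dlogits)
                opt.step()
                total_loss += loss * len(idx)
                correct += int((probs.argmax(axis=1) == yb).sum())
            log.append({"epoch": epoch + 1, "loss": total_loss / n, "accuracy": correct / n})
            if verbose:
                print(f"epoch {epoch + 1:3d}  loss {log[-1]['loss']:.4f}  acc {log[-1]['accuracy']:.3f}")
        return TrainedModel(spec=spec, network=net, class_order=CLASS_ORDER,
                            training_log=log, input_shape=tuple(x.shape[1:]),
                            channels=channels, seed=seed)


@dataclass
class TrainedModel:
    """Results of a CNN-LSTM fit: learned weights plus the training log."""

    spec: ModelSpec
    network: nn.Sequential
    class_order: tuple[int, ...]
    training_log: list[dict]
    input_shape: tuple[int, int]
    channels: list[str] | None = None
    seed: int = 0

    def predict(self, data, batch_size: int = 64):
        """Predict technique codes; returns ``(labels, probabilities)``.

        Dropout is disabled, so prediction is deterministic.
        """
        x, _, _ = _as_xy(data)
        if tuple(x.shape[1:]) != tuple(self.input_shape):
            raise ValidationError(
                f"input cycles have shape {tuple(x.shape[1:])} but the model was "
                f"trained on {tuple(self.input_shape)}"
            )
        probs = np.empty((x.shape[0], self.spec.n_classes), dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            logits = self.network.forward(x[start:start + batch_size], train=False)
            probs[start:start + len(logits)] = nn.softmax(logits.astype(np.float64))
        labels = np.asarray(self.class_order)[probs.argmax(axis=1)]
        return labels, probs

    @property
    def final_loss(self) -> float:
        return self.training_log[-1]["loss"]

    @property
    def final_accuracy(self) -> float:
        return self.training_log[-1]["accuracy"]

    def summary(self) -> pd.DataFrame:
        """Per-epoch training loss and accuracy as a table."""
        return pd.DataFrame(self.training_log)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **{f"p{i}": w for i, w in enumerate(self.network.get_weights())})
        sidecar = {
            "spec": self.spec.to_dict(),
            "class_order": list(self.class_order),
            "input_shape": list(self.input_shape),
            "channels": self.channels,
            "seed": self.seed,
            "training_log": self.training_log,
        }
        (out / "model.json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(in_dir) -> "TrainedModel":
        src = Path(in_dir)
        sidecar = json.loads((src / "model.json").read_text())
        spec = ModelSpec.from_dict(sidecar["spec"])
        net = build_network(spec, tuple(sidecar["input_shape"]), np.random.default_rng(0))
        with np.load(src / "weights.npz") as z:
            net.set_weights([z[f"p{i}"] for i in range(len(z.files))])
        return TrainedModel(
            spec=spec, network=net, class_order=tuple(sidecar["class_order"]),
            training_log=sidecar["training_log"], input_shape=tuple(sidecar["input_shape"]),
            channels=sidecar["channels"], seed=sidecar["seed"],
        )
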