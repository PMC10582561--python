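"""Compact fully connected 3-class network on the six pixel features.

The reference architecture takes the 6 normalized features through seven
hidden ReLU layers of widths (24, 24, 24, 24, 24, 16, 46) to a 3-way
softmax, for exactly 3891 trainable parameters — deliberately small for a
tabular problem with tens of thousands of rows.  Training uses Adam on
categorical cross-entropy with an L2 weight penalty, inverted dropout on
the hidden activations, and early stopping on validation loss with
best-weight restoration.  A single integer seed makes initialisation,
shuffling and dropout masks reproducible.

The network is implemented directly on numpy arrays: at this size a
framework adds nothing, and explicit code keeps the run bit-reproducible
on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mapbuild import FEATURES, Normalizer

__all__ = [
    "CLASSES",
    "MLPSpec",
    "TrainedModel",
    "count_params",
    "train",
    "predict_pixels",
    "confusion_matrix",
]

CLASSES = ("M0", "M1", "M2")


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and optimisation hyper-parameters.

    ``hidden_widths`` must have exactly seven entries for the reference
    topology; other depths are accepted for experiments but flagged via
    ``strict_depth``.
    """

    hidden_widths: tuple[int, ...] = (24, 24, 24, 24, 24, 16, 46)
    input_dim: int = 6
    output_dim: int = 3
    dropout_rate: float = 0.2
    l2_coefficient: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    strict_depth: bool = True

    def __post_init__(self) -> None:
        if self.strict_depth and len(self.hidden_widths) != 7:
            raise ValueError(
                f"reference topology has 7 hidden layers, got {len(self.hidden_widths)}"
            )
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_widths, self.output_dim]


def count_params(spec: MLPSpec) -> int:
    """Trainable parameter count: sum over layers of (fan_in + 1) * fan_out."""
    dims = spec.layer_dims
    return int(sum((dims[i] + 1) * dims[i + 1] for i in range(len(dims) - 1)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(spec: MLPSpec, rng: np.random.Generator):
    dims = spec.layer_dims
    weights, biases = [], []
    for i in range(len(dims) - 1):
        # He initialisation for the ReLU stack
        scale = np.sqrt(2.0 / dims[i])
        weights.append(rng.normal(0.0, scale, size=(dims[i], dims[i + 1])))
        biases.append(np.zeros(dims[i + 1]))
    return weights, biases


def _forward(weights, biases, X, dropout_rate=0.0, rng=None):
    """Forward pass; returns (probabilities, per-layer activations, masks)."""
    acts = [X]
    masks = []
    a = X
    n_layers = len(weights)
    for i in range(n_layers - 1):
        a = np.maximum(a @ weights[i] + biases[i], 0.0)
        if dropout_rate > 0.0 and rng is not None:
            keep = rng.random(a.shape) >= dropout_rate
            a = a * keep / (1.0 - dropout_rate)  # inverted dropout
            masks.append(keep)
        else:
            masks.append(None)
        acts.append(a)
    probs = _softmax(a @ weights[-1] + biases[-1])
    return probs, acts, masks


@dataclass
class TrainedModel:
    """Trained network with its preprocessing state and learning curves."""

    spec: MLPSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: tuple[str, ...] = CLASSES
    normalizer: Normalizer | None = None
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        probs, _, _ = _forward(self.weights, self.biases, X)
        return probs

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([self.classes[i] for i in probs.argmax(axis=1)])

    # -- persistence -------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(directory / "weights.npz", **arrays)
        meta = {"spec": asdict(self.spec), "classes": list(self.classes),
                "history": self.history}
        (directory / "model.json").write_text(json.dumps(meta))
        if self.normalizer is not None:
            (directory / "normalizer.json").write_text(self.normalizer.to_json())

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec_d = meta["spec"]
        spec_d["hidden_widths"] = tuple(spec_d["hidden_widths"])
        spec = MLPSpec(**spec_d)
        data = np.load(directory / "weights.npz")
        n = len(spec.layer_dims) - 1
        weights = [data[f"W{i}"] for i in range(n)]
        biases = [data[f"b{i}"] for i in range(n)]
        norm = None
        norm_path = directory / "normalizer.json"
        if norm_path.exists():
            norm = Normalizer.from_json(norm_path.read_text())
        return cls(spec=spec, weights=weights, biases=biases,
                   classes=tuple(meta["classes"]), normalizer=norm,
                   history=meta.get("history", {}))


def _records_to_xy(records: pd.DataFrame, classes=CLASSES, features=FEATURES):
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(classes)}
    y = records["Category"].map(idx).to_numpy()
    if np.any(pd.isna(y)):
        bad = sorted(set(records["Category"]) - set(classes))
        raise ValueError(f"unknown class labels {bad}")
    return X, y.astype(int)


def _loss_acc(weights, biases, X, y, l2):
    probs, _, _ = _forward(weights, biases, X)
    n = len(y)
    ce = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    if l2 > 0:
        ce += l2 * float(sum(np.sum(w * w) for w in weights))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return ce, acc


def train(
    spec: MLPSpec,
    train_records: pd.DataFrame,
    val_records: pd.DataFrame,
    classes: tuple[str, ...] = CLASSES,
    normalizer: Normalizer | None = None,
    features: tuple[str, ...] = FEATURES,
    verbose: bool = False,
) -> TrainedModel:
    """Train the network on normalized pixel records.

    Expects the feature columns already normalized; attach the fitted
    :class:`~nanovote.mapbuild.Normalizer` so the model can be applied to
    raw records later.  Early stopping monitors validation loss with
    ``spec.patience`` epochs of grace and restores the best weights.

    Raises ``ValueError`` if a class is absent from the training records.
    """
    X, y = _records_to_xy(train_records, classes, features)
    Xv, yv = _records_to_xy(val_records, classes, features)
    present = set(y.tolist())
    if present != set(range(len(classes))):
        missing = [classes[i] for i in range(len(classes)) if i not in present]
        raise ValueError(f"classes absent from training data: {missing}")

    rng = np.random.default_rng(spec.seed)
    weights, biases = _init_weights(spec, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_val = np.inf
    best_state = None
    stall = 0
    n = len(y)
    n_layers = len(weights)

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = X[idx], y[idx]
            probs, acts, masks = _forward(
                weights, biases, xb, spec.dropout_rate, rng
            )
            # backprop of cross-entropy + L2
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            g_w = [None] * n_layers
            g_b = [None] * n_layers
            for i in range(n_layers - 1, -1, -1):
                g_w[i] = acts[i].T @ grad + 2.0 * spec.l2_coefficient * weights[i]
                g_b[i] = grad.sum(axis=0)
                if i > 0:
                    grad = grad @ weights[i].T
                    grad *= acts[i] > 0
                    if masks[i - 1] is not None:
                        grad *= masks[i - 1] / (1.0 - spec.dropout_rate)
            t += 1
            corr1 = 1.0 - beta1**t
            corr2 = 1.0 - beta2**t
            for i in range(n_layers):
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * g_w[i]
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * g_w[i] ** 2
                weights[i] -= spec.learning_rate * (m_w[i] / corr1) / (
                    np.sqrt(v_w[i] / corr2) + eps
                )
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * g_b[i]
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * g_b[i] ** 2
                biases[i] -= spec.learning_rate * (m_b[i] / corr1) / (
                    np.sqrt(v_b[i] / corr2) + eps
                )

        tr_loss, tr_acc = _loss_acc(weights, biases, X, y, spec.l2_coefficient)
        va_loss, va_acc = _loss_acc(weights, biases, Xv, yv, spec.l2_coefficient)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  train {tr_loss:.4f}/{tr_acc:.3f}"
                f"  val {va_loss:.4f}/{va_acc:.3f}"
            )
        if va_loss < best_val - 1e-6:
            best_val = va_loss
            best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break

    if best_state is not None:
        weights, biases = best_state
    return TrainedModel(
        spec=spec, weights=weights, biases=biases, classes=classes,
        normalizer=normalizer, history=history,
    )


def predict_pixels(
    model: TrainedModel, records: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
) -> pd.DataFrame:
    """Per-record class probabilities and argmax label.

    Returns a copy of ``records`` with columns ``p_M0, p_M1, p_M2`` (one
    per class) and ``predicted``.
    """
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    probs = model.predict_proba(X)
    out = records.copy()
    for i, c in enumerate(model.classes):
        out[f"p_{c}"] = probs[:, i]
    out["predicted"] = [model.classes[i] for i in probs.argmax(axis=1)]
    return out


def confusion_matrix(
    predicted, truth, classes: tuple[str, ...] = CLASSES
) -> np.ndarray:
    """Row-normalized confusion matrix; rows = true class, columns =
    predicted class, diagonal = per-class accuracy."""
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k))
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        missing = [classes[i] for i in range(k) if row_sums[i, 0] == 0]
        raise ValueError(f"no records with true class {missing}")
    return counts / row_sums
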