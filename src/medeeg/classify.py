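"""Compact MLP classifier shared by all three pipelines.

A two-hidden-layer (20, 20) perceptron with logistic activations and a
single sigmoid output, trained with adaptive-moment gradient descent on a
binary cross-entropy objective.  Features are standardized with
training-set mean/SD stored in the model.  Prediction is a deterministic
forward pass through the stored weights; probability ties at exactly 0.5
resolve to class 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .containers import FeatureTable
from .features import FEATURE_CAP


@dataclass(frozen=True)
class MLPSpec:
    hidden_layers: tuple[int, int] = (20, 20)
    max_epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    early_stopping: bool = True
    validation_fraction: float = 0.1
    patience: int = 50

    def __post_init__(self) -> None:
        if len(self.hidden_layers) != 2 or any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden_layers must be two positive widths")
        if self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


@dataclass
class TrainedModel:
    """Weights + standardization constants; prediction is deterministic."""

    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    mean: np.ndarray
    sd: np.ndarray
    spec: MLPSpec
    n_iter: int = 0
    final_loss: float = float("nan")

    @property
    def n_features(self) -> int:
        return self.coefs[0].shape[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(meditation) per row."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError("feature width does not match model")
        h = (x - self.mean) / self.sd
        for w, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = _sigmoid(h @ w + b)
        out = _sigmoid(h @ self.coefs[-1] + self.intercepts[-1])
        return out.ravel()

    def predict(self, x: np.ndarray) -> np.ndarray:
        """0/1 labels; p = 0.5 exactly resolves to class 0."""
        return (self.predict_proba(x) > 0.5).astype(np.int64)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train(features: FeatureTable, spec: MLPSpec = MLPSpec()) -> TrainedModel:
    """Train the MLP on a feature table; reproducible given ``spec.seed``."""
    x, y = features.X, features.labels
    if features.n_features > FEATURE_CAP:
        raise ValueError(f"feature count exceeds the cap of {FEATURE_CAP}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns carry no information; leave centered
    xs = (x - mean) / sd
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation="logistic",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.max_epochs,
        early_stopping=spec.early_stopping,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=spec.patience,
        random_state=int(spec.seed) % (2**31),
    )
    with warnings.catch_warnings():
        # the epoch budget is part of the training contract; hitting it is
        # expected behaviour, not a defect worth a warning per split
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xs, y)
    return TrainedModel(
        coefs=[np.asarray(c) for c in clf.coefs_],
        intercepts=[np.asarray(b) for b in clf.intercepts_],
        mean=mean, sd=sd, spec=spec,
        n_iter=int(clf.n_iter_), final_loss=float(clf.loss_),
    )


def accuracy(model: TrainedModel, features: FeatureTable) -> float:
    """Percentage of correctly classified epochs, in [0, 100]."""
    if len(features) == 0:
        raise ValueError("empty feature table")
    pred = model.predict(features.X)
    return 100.0 * float(np.mean(pred == features.labels))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist weights, standardization constants and spec to one .npz file."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"mean": model.mean, "sd": model.sd}
    for i, (c, b) in enumerate(zip(model.coefs, model.intercepts)):
        arrays[f"coef_{i}"] = c
        arrays[f"intercept_{i}"] = b
    meta = dict(asdict(model.spec), n_layers=len(model.coefs),
                n_iter=model.n_iter, final_loss=model.final_loss)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode("utf-8"))
        n_layers = meta.pop("n_layers")
        n_iter = meta.pop("n_iter")
        final_loss = meta.pop("final_loss")
        meta["hidden_layers"] = tuple(meta["hidden_layers"])
        return TrainedModel(
            coefs=[z[f"coef_{i}"] for i in range(n_layers)],
            intercepts=[z[f"intercept_{i}"] for i in range(n_layers)],
            mean=z["mean"], sd=z["sd"], spec=MLPSpec(**meta),
            n_iter=n_iter, final_loss=final_loss,
        )
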