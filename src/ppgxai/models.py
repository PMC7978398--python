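"""A small trainable 1D residual CNN and its training/evaluation protocol.

The classifier predicts whether a PPG segment is artifact-free (the positive
class) or artifactual (the negative class). Defaults mirror the reference
protocol: Glorot-uniform kernels of size 80, binary cross-entropy, Adam at
1e-4, 50 epochs, with the model from the best-validation-accuracy epoch kept
as the final model. The network itself is a deliberately reduced residual
net so it trains on a single CPU in minutes; depth/width only scale capacity
and are irrelevant to the correctness of the explainability metrics built on
top of it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from ._nn import Adam, ResNet1d
from .core import LabeledDataset

__all__ = [
    "TrainConfig",
    "PerformanceReport",
    "PpgCnnClassifier",
    "build_cnn1d",
    "train",
    "evaluate",
]

#: The positive class for sensitivity/NPV bookkeeping, asserted in one place:
#: artifact-free segments are "positive", artifactual segments "negative".
POSITIVE_CLASS = 1


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    depth: int = 2
    kernel_size: int = 80
    channels: int = 8
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            path.write_text(yaml.safe_dump(asdict(self)))
        else:
            path.write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            return cls(**yaml.safe_load(path.read_text()))
        return cls(**json.loads(path.read_text()))


@dataclass
class PerformanceReport:
    """Confusion-matrix rates at a fixed probability threshold.

    Sensitivity is computed over artifact-free (positive) records,
    specificity over artifactual (negative) records, and NPV = TN/(TN+FN).
    A rate whose denominator is zero is reported as NaN (undefined), not 0.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    npv: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return asdict(self)


class PpgCnnClassifier(ClassifierMixin, BaseEstimator):
    """Reduced 1D residual CNN for PPG quality classification.

    Parameters
    ----------
    depth : int
        Number of residual blocks.
    kernel_size : int
        Convolution kernel length in taps (reference value: 80).
    channels : int
        Feature channels throughout the network.
    learning_rate, epochs, batch_size : Adam/BCE training loop settings.
    validation_fraction : float
        Stratified fraction of the training data held out per-epoch model
        selection when no explicit validation set is passed to :meth:`fit`.
    random_state : int
        Seeds initialization, the validation split, and batch shuffling.

    Attributes
    ----------
    model_ : ResNet1d
        The fitted network (weights from the best-validation epoch).
    history_ : pandas.DataFrame
        Per-epoch training loss and validation accuracy.
    best_epoch_ : int
        1-based epoch whose weights were kept (highest validation accuracy,
        earliest epoch on ties).
    """

    def __init__(
        self,
        depth: int = 2,
        kernel_size: int = 80,
        channels: int = 8,
        learning_rate: float = 1e-4,
        epochs: int = 50,
        batch_size: int = 32,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.depth = depth
        self.kernel_size = kernel_size
        self.channels = channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "training labels must contain both classes {0, 1} "
                f"(got {classes.tolist()})"
            )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            X, y, X_val, y_val = _stratified_split(X, y, self.validation_fraction, rng)
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=int)

        net = ResNet1d(
            n_input=X.shape[1],
            depth=self.depth,
            kernel_size=self.kernel_size,
            channels=self.channels,
            seed=int(rng.integers(2**31 - 1)),
        )
        opt = Adam(net, lr=self.learning_rate)

        n = X.shape[0]
        best_acc, best_weights, best_epoch = -np.inf, None, -1
        rows = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                z = net.logits(X[idx])
                yb = y[idx]
                # stable BCE from logits
                losses.append(
                    float(np.mean(np.maximum(z, 0) - z * yb + np.log1p(np.exp(-np.abs(z)))))
                )
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))
                net.zero_grad()
                net.backward((p - yb) / len(idx))
                opt.step()
            val_acc = float(np.mean((net.predict_proba(X_val) >= 0.5) == (y_val == 1)))
            rows.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
            )
            if val_acc > best_acc:  # strict: earliest epoch wins ties
                best_acc, best_epoch = val_acc, epoch
                best_weights = net.get_weights()

        net.set_weights(best_weights)
        self.model_ = net
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch
        self.best_val_accuracy_ = best_acc
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.logits(X)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- gradient access for saliency --------------------------------------
    def input_gradient(self, X, guided: bool = False) -> np.ndarray:
        """Gradient of the artifact-free probability w.r.t. each input sample."""
        check_is_fitted(self, "model_")
        return self.model_.input_gradient(np.asarray(X, dtype=float), guided=guided)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "model_")
        weights = self.model_.get_weights()
        np.savez(
            path,
            *weights,
            _config=json.dumps({**self.get_params(), **self.model_.get_config()}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PpgCnnClassifier":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["_config"]))
            weights = [data[k] for k in data.files if k != "_config"]
        net_cfg = {
            k: config.pop(k) for k in ["n_input", "seed", "activation"]
        }
        est_params = {k: config[k] for k in cls().get_params()}
        clf = cls(**est_params)
        net = ResNet1d(
            n_input=net_cfg["n_input"],
            depth=est_params["depth"],
            kernel_size=est_params["kernel_size"],
            channels=est_params["channels"],
            seed=net_cfg["seed"],
            activation=net_cfg["activation"],
        )
        net.set_weights(weights)
        clf.model_ = net
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = net.n_input
        return clf


def _stratified_split(X, y, fraction, rng):
    """Split off a stratified validation fraction; returns train + val arrays."""
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * idx.size)))
        val_idx.extend(rng.permutation(idx)[:k])
    val_idx = np.sort(val_idx)
    train_idx = np.setdiff1d(np.arange(y.size), val_idx)
    return X[train_idx], y[train_idx], X[val_idx], y[val_idx]


def build_cnn1d(
    n_input: int,
    depth: int = 2,
    kernel_size: int = 80,
    channels: int = 8,
    seed: int = 0,
) -> ResNet1d:
    """Construct an untrained residual 1D CNN with deterministic
    Glorot-uniform initialization."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return ResNet1d(
        n_input=n_input, depth=depth, kernel_size=kernel_size, channels=channels, seed=seed
    )


def train(
    train_set: LabeledDataset,
    val_set: LabeledDataset | None,
    config: TrainConfig | None = None,
) -> tuple[PpgCnnClassifier, pd.DataFrame]:
    """Train a classifier on a labeled dataset; returns (classifier, history).

    If ``val_set`` is None a stratified ``validation_fraction`` split of the
    training set is used for per-epoch model selection.
    """
    config = config or TrainConfig()
    clf = PpgCnnClassifier(
        depth=config.depth,
        kernel_size=config.kernel_size,
        channels=config.channels,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        validation_fraction=config.validation_fraction,
        random_state=config.seed,
    )
    if val_set is None:
        clf.fit(train_set.X, train_set.y)
    else:
        clf.fit(train_set.X, train_set.y, X_val=val_set.X, y_val=val_set.y)
    return clf, clf.history_


def evaluate(model, test_set, y=None, threshold: float = 0.5) -> PerformanceReport:
    """Confusion-matrix performance at a probability threshold.

    ``test_set`` may be a :class:`~ppgxai.core.LabeledDataset` or a plain
    signal matrix accompanied by ``y``. Artifact-free is the positive class.
    """
    if isinstance(test_set, LabeledDataset):
        X, y = test_set.X, test_set.y
    else:
        X = np.asarray(test_set, dtype=float)
        y = np.asarray(y)
    y = y.astype(int)
    prob = model.predict_proba(X)
    prob_pos = prob[:, 1] if prob.ndim == 2 else prob
    pred = (prob_pos >= threshold).astype(int)

    tp = int(np.sum((pred == 1) & (y == POSITIVE_CLASS)))
    fn = int(np.sum((pred == 0) & (y == POSITIVE_CLASS)))
    tn = int(np.sum((pred == 0) & (y != POSITIVE_CLASS)))
    fp = int(np.sum((pred == 1) & (y != POSITIVE_CLASS)))

    def rate(num, den):
        return num / den if den > 0 else math.nan

    return PerformanceReport(
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        accuracy=rate(tp + tn, tp + tn + fp + fn),
        npv=rate(tn, tn + fn),
        threshold=threshold,
    )
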