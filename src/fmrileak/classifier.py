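"""Binary slice classifiers with a scikit-learn estimator interface.

Two architectures share the same modified head (linear -> ReLU ->
dropout -> linear to 2 logits):

* ``tinycnn`` — a small three-block CNN implemented in numpy, trainable on
  a laptop CPU in seconds. All desk-scale experiments and every test run
  on it.
* ``resnet18`` — the standard 18-weight-layer residual network with its
  final fully connected layer replaced by the same head and all layers
  left trainable for fine-tuning. It requires the optional ``torch`` /
  ``torchvision`` dependencies and a GPU-scale budget, and is provided for
  study-scale runs only.

Training minimizes softmax cross-entropy with Adam. Given a seed and fixed
data, initialization, batch order, dropout masks, the loss history and all
predictions are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, TinyCNNNet, cross_entropy_grad, softmax
from ._rng import derive_seed

__all__ = ["Hyperparams", "TinyCNNClassifier", "build_model", "train", "predict"]


@dataclasses.dataclass(frozen=True)
class Hyperparams:
    """Training configuration.

    Defaults mirror the fine-tuning recipe the harness replicates: dropout
    0.2, batch size 256, learning rate 1e-5. Desk-scale tinycnn runs
    override the learning rate (1e-3) and epoch count, since a small net
    trained from scratch needs a larger step than a pretrained ResNet.
    """

    architecture: str = "tinycnn"
    pretrained: bool = False
    dropout: float = 0.2
    batch_size: int = 256
    learning_rate: float = 1e-5
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("tinycnn", "resnet18"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


class TinyCNNClassifier(BaseEstimator, ClassifierMixin):
    """Three-block numpy CNN for binary slice classification.

    Parameters
    ----------
    dropout : float, default 0.2
        Drop probability in the dense head (inverted dropout).
    batch_size : int, default 256
        Mini-batch size; auto-clamped (with a warning) to the dataset size.
    learning_rate : float, default 1e-3
        Adam step size.
    epochs : int, default 5
        Full passes over the training data. ``epochs=0`` leaves the
        freshly initialized network untouched (useful as a chance-level
        control).
    seed : int, default 0
        Seeds initialization, batch shuffling and dropout masks.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels.
    history_ : list of dict
        Per-epoch ``{"epoch", "loss", "accuracy"}`` on the training data.
    checksum_ : str
        SHA-256 over all parameters after fitting.
    """

    def __init__(self, dropout=0.2, batch_size=256, learning_rate=1e-3, epochs=5, seed=0):
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed

    # ------------------------------------------------------------------
    def _validate_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_samples, channels, H, W), got shape {X.shape}")
        if len(X) == 0:
            raise ValueError("empty slice collection")
        return X

    def fit(self, X, y):
        """Train on prepared slices X (n, C, S, S) and labels y."""
        Hyperparams(
            dropout=self.dropout,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed,
        )  # range validation
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classifier needs exactly 2 classes in the training data, "
                f"got {list(self.classes_)}"
            )
        y_idx = np.searchsorted(self.classes_, y)

        batch = self.batch_size
        if batch > len(X):
            warnings.warn(
                f"batch_size {batch} exceeds dataset size {len(X)}; clamping",
                stacklevel=2,
            )
            batch = len(X)

        self.net_ = TinyCNNNet(X.shape[1:], self.dropout, derive_seed(self.seed, "init"))
        opt = Adam(self.net_.parameters(), self.learning_rate)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(derive_seed(self.seed, "shuffle"))
        )
        self.history_ = []
        for epoch in range(self.epochs):
            perm = shuffle_rng.permutation(len(X))
            losses, hits, seen = [], 0, 0
            for start in range(0, len(X), batch):
                idx = perm[start : start + batch]
                logits = self.net_.forward(X[idx], train=True)
                loss, dlogits = cross_entropy_grad(logits, y_idx[idx])
                self.net_.backward(dlogits)
                opt.step(self.net_.gradients())
                losses.append(loss * len(idx))
                hits += int((logits.argmax(axis=1) == y_idx[idx]).sum())
                seen += len(idx)
            self.history_.append(
                {
                    "epoch": epoch,
                    "loss": float(np.sum(losses) / seen),
                    "accuracy": hits / seen,
                }
            )
        self.checksum_ = self.net_.checksum()
        return self

    def _forward_batched(self, X, batch=512):
        outs = [self.net_.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X):
        """Class-membership scores in [0, 1], columns ordered by classes_."""
        check_is_fitted(self, "net_")
        return softmax(self._forward_batched(self._validate_X(X)))

    def predict(self, X):
        """Argmax labels; exact ties resolve to the first (class-0) label."""
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] > proba[:, 0]).astype(int)]

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint parameters (npz) plus a JSON sidecar of metadata."""
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state())
        sidecar = {
            "architecture": "tinycnn",
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "input_shape": list(self.net_.input_shape),
            "history": self.history_,
            "checksum": self.checksum_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TinyCNNClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        est = cls(**sidecar["params"])
        est.classes_ = np.array(sidecar["classes"])
        est.net_ = TinyCNNNet(
            tuple(sidecar["input_shape"]), est.dropout, derive_seed(est.seed, "init")
        )
        with np.load(path.with_suffix(".npz")) as state:
            est.net_.load_state(dict(state))
        est.history_ = sidecar["history"]
        est.checksum_ = est.net_.checksum()
        if est.checksum_ != sidecar["checksum"]:
            raise ValueError(f"checkpoint {path} failed its checksum")
        return est


def _build_resnet18(hp: Hyperparams):
    try:
        import torch.nn as nn
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the resnet18 architecture requires the optional torch/torchvision "
            "dependencies (pip install 'fmrileak[torch]'); use architecture='tinycnn' "
            "for desk-scale runs"
        ) from exc
    weights = torchvision.models.ResNet18_Weights.DEFAULT if hp.pretrained else None
    model = torchvision.models.resnet18(weights=weights)
    model.fc = nn.Sequential(
        nn.Linear(model.fc.in_features, model.fc.in_features),
        nn.ReLU(),
        nn.Dropout(hp.dropout),
        nn.Linear(model.fc.in_features, 2),
    )
    for p in model.parameters():  # all layers unfrozen for fine-tuning
        p.requires_grad = True
    return model


def build_model(hp: Hyperparams):
    """Instantiate the untrained model named by ``hp.architecture``."""
    if hp.architecture == "tinycnn":
        return TinyCNNClassifier(
            dropout=hp.dropout,
            batch_size=hp.batch_size,
            learning_rate=hp.learning_rate,
            epochs=hp.epochs,
            seed=hp.seed,
        )
    if hp.architecture == "resnet18":
        return _build_resnet18(hp)
    raise ValueError(f"unknown architecture {hp.architecture!r}")


def train(model: TinyCNNClassifier, X: np.ndarray, y: Sequence) -> TinyCNNClassifier:
    """Fit ``model`` on prepared slices; thin wrapper over ``fit``."""
    return model.fit(X, y)


def predict(model: TinyCNNClassifier, X: np.ndarray):
    """Per-slice labels and class-1 scores from a fitted model."""
    proba = model.predict_proba(X)
    labels = model.classes_[(proba[:, 1] > proba[:, 0]).astype(int)]
    return labels, proba[:, 1]
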