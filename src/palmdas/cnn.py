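"""The two acoustic-image CNN classifiers, as scikit-learn-style estimators.

Both branches share one topology — conv → pool → conv → pool → flatten →
dense(50, ReLU) → dense(1, sigmoid) — and differ only in the first
convolution: the temporal branch (10x500 inputs) uses 16 filters of 3x50,
the spectral branch (10x250 inputs) 32 filters of 3x5; the second
convolution is 32 filters of 3x3 in both, all stride 1x1, valid padding,
with 2x2 max-pools.  Training is Adam on binary cross-entropy with an
internal validation split, keeping the best-validation-accuracy checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = ["ModelSpec", "default_spec", "build_model", "layer_output_shapes",
           "ImageCNNClassifier"]

INPUT_SHAPES = {"temporal": (10, 500), "spectral": (10, 250)}


@dataclass(frozen=True)
class ModelSpec:
    """Layer-by-layer description of one branch."""

    branch: Literal["temporal", "spectral"]
    layers: tuple[tuple, ...]

    @property
    def input_shape(self) -> tuple[int, int]:
        return INPUT_SHAPES[self.branch]


def default_spec(branch: str) -> ModelSpec:
    if branch not in INPUT_SHAPES:
        raise ValueError(f"branch must be 'temporal' or 'spectral', got {branch!r}")
    first = ("conv", 16, (3, 50), (1, 1), "relu") if branch == "temporal" \
        else ("conv", 32, (3, 5), (1, 1), "relu")
    return ModelSpec(
        branch=branch,
        layers=(
            first,
            ("pool", (2, 2)),
            ("conv", 32, (3, 3), (1, 1), "relu"),
            ("pool", (2, 2)),
            ("flatten",),
            ("dense", 50, "relu"),
            ("dense", 1, "sigmoid"),
        ),
    )


def layer_output_shapes(spec: ModelSpec) -> list[tuple]:
    """Shape after each spec layer (excluding batch), by shape arithmetic."""
    h, w = spec.input_shape
    c = 1
    shapes: list[tuple] = []
    flat: int | None = None
    for layer in spec.layers:
        kind = layer[0]
        if kind == "conv":
            _, filters, (kh, kw), (sh, sw), _ = layer
            if h < kh or w < kw:
                raise ValueError(f"kernel {kh}x{kw} larger than input {h}x{w}")
            h, w, c = (h - kh) // sh + 1, (w - kw) // sw + 1, filters
            shapes.append((h, w, c))
        elif kind == "pool":
            (ph, pw) = layer[1]
            h, w = h // ph, w // pw
            if h < 1 or w < 1:
                raise ValueError("pooled away to nothing")
            shapes.append((h, w, c))
        elif kind == "flatten":
            flat = h * w * c
            shapes.append((flat,))
        elif kind == "dense":
            flat = layer[1]
            shapes.append((flat,))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    return shapes


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the branch network with seeded initial weights.

    Two builds from the same (spec, seed) produce identical weights.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.input_shape
    c = 1
    layers: list = []
    flat = None
    first_conv = True
    for layer in spec.layers:
        kind = layer[0]
        if kind == "conv":
            _, filters, (kh, kw), (sh, sw), act = layer
            if (sh, sw) != (1, 1):
                raise ValueError("only stride 1x1 convolutions are supported")
            conv = nn.Conv2D(kh, kw, c, filters, rng, first_layer=first_conv)
            first_conv = False
            layers.append(conv)
            h, w = conv.output_shape(h, w)
            c = filters
            if act == "relu":
                layers.append(nn.ReLU())
        elif kind == "pool":
            layers.append(nn.MaxPool2x2())
            h, w = h // 2, w // 2
        elif kind == "flatten":
            layers.append(nn.Flatten())
            flat = h * w * c
        elif kind == "dense":
            units = layer[1]
            layers.append(nn.Dense(flat, units, rng))
            if layer[2] == "relu":
                layers.append(nn.ReLU())
            flat = units
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    return nn.Sequential(layers)


class ImageCNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary infested/healthy classifier for one image branch.

    Parameters
    ----------
    branch : {'temporal', 'spectral'}
        Which image kind this classifier consumes: 10x500 band-passed
        waveform images or 10x250 one-sided spectra.
    epochs, batch_size, learning_rate, patience
        Adam training regime; training stops early when validation loss
        stalls for ``patience`` epochs and the best-validation-accuracy
        weights are kept.
    validation_fraction : float
        Fraction of ``fit`` data held out for the validation curve when no
        explicit validation set is passed.
    random_state : int
        Seeds weight initialization, the validation split and shuffling.

    Attributes
    ----------
    model_ : trained network
    history_ : dict of per-epoch train/val loss and accuracy
    classes_ : label vocabulary; ``classes_[1]`` is the positive (infested) class
    n_params_ : trainable parameter count
    """

    def __init__(
        self,
        branch: str = "temporal",
        epochs: int = 8,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.2,
        patience: int = 3,
        random_state: int = 0,
        threshold: float = 0.5,
    ):
        self.branch = branch
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state
        self.threshold = threshold

    def _validate_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        want = INPUT_SHAPES[self.branch]
        if x.ndim != 3 or x.shape[1:] != want:
            raise ValueError(f"{self.branch} branch expects (n, {want[0]}, {want[1]}) images, "
                             f"got {x.shape}")
        return x[..., None]  # channels-last

    def fit(self, X, y, X_val=None, y_val=None):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        spec = default_spec(self.branch)
        x = self._validate_x(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classifier needs 2 classes, got {self.classes_}")
        yb = (y == self.classes_[1]).astype(np.float32)
        if X_val is not None:
            xv = self._validate_x(X_val)
            yv = (np.asarray(y_val) == self.classes_[1]).astype(np.float32)
            xt, yt = x, yb
        else:
            if self.epochs > 0 and not 0 < self.validation_fraction < 1:
                raise ValueError("validation_fraction must be in (0, 1)")
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(x))
            n_val = max(1, int(round(self.validation_fraction * len(x))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            xt, yt, xv, yv = x[tr_idx], yb[tr_idx], x[val_idx], yb[val_idx]
        self.spec_ = spec
        self.model_ = build_model(spec, seed=self.random_state)
        self.n_params_ = self.model_.n_params()
        self.history_ = nn.train_loop(
            self.model_, xt, yt, xv, yv,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.random_state + 1,
            patience=self.patience,
        )
        self.best_epoch_ = int(np.argmax(self.history_["val_acc"])) if self.history_["val_acc"] else -1
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p = self.model_.predict_proba(self._validate_x(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_logits(self._validate_x(X))
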