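"""Convolutional mask classifier exposing the 3-node shape feature vector.

A small CNN trained to classify normalized 64 x 64 cell masks.  The three
pre-softmax activations F = (F1, F2, F3) of the final layer are the shape
features; the 256-unit dense layer provides the higher-dimensional
alternative feature space.  Implemented as a scikit-learn style estimator:
``fit`` / ``predict`` / ``predict_proba`` / ``transform`` (features),
``get_params`` / ``set_params``, fitted attributes with trailing
underscores, so it composes with sklearn model selection.

Architecture (frozen default):
    input 64x64x1
    -> conv(16, 3x3) + relu -> maxpool 3x3
    -> conv(32, 3x3) + relu -> maxpool 3x3
    -> flatten -> dense(256) + relu -> dense(32) + tanh
    -> dense(n_classes, linear) -> softmax
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ..pipeline import FRAME_SIZE, NormalizedMask
from . import nn

__all__ = ["MaskClassifier", "augment_dataset", "NotTrainedError"]


class NotTrainedError(RuntimeError):
    pass


def _as_stack(masks) -> np.ndarray:
    """Accept (n, 64, 64) arrays or lists of arrays / NormalizedMask."""
    if isinstance(masks, np.ndarray) and masks.ndim == 3:
        stack = masks
    else:
        stack = np.stack([m.mask if isinstance(m, NormalizedMask) else np.asarray(m) for m in masks])
    if stack.shape[1:] != (FRAME_SIZE, FRAME_SIZE):
        raise ValueError(f"masks must be {FRAME_SIZE}x{FRAME_SIZE}, got {stack.shape[1:]}")
    return stack.astype(float)


def augment_dataset(
    masks, labels, max_angle: float = 5.0, target_count: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pad every class to ``target_count`` with small random rotations.

    Rotation angles are drawn uniformly from (-max_angle, +max_angle) degrees;
    the augmented copies are re-thresholded binary masks.  Deterministic for a
    fixed seed.
    """
    from skimage import transform as sktransform

    stack = _as_stack(masks)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ValueError("every class needs at least one mask")
    if target_count is None:
        target_count = int(counts.max())
    if target_count < counts.max():
        raise ValueError("target_count must be at least the largest class size")
    out_masks = [stack]
    out_labels = [labels]
    for cls, count in zip(classes, counts):
        need = target_count - count
        if need <= 0:
            continue
        pool = stack[labels == cls]
        picks = rng.integers(0, len(pool), size=need)
        angles = rng.uniform(-max_angle, max_angle, size=need)
        rotated = np.stack(
            [
                sktransform.rotate(pool[i], a, order=1) >= 0.5 if a != 0.0 else pool[i] >= 0.5
                for i, a in zip(picks, angles)
            ]
        ).astype(float)
        out_masks.append(rotated)
        out_labels.append(np.full(need, cls, dtype=labels.dtype))
    return np.concatenate(out_masks), np.concatenate(out_labels)


class MaskClassifier(BaseEstimator, ClassifierMixin):
    """CNN shape classifier over normalized binary masks.

    Parameters
    ----------
    epochs : number of passes over the training set (the reference protocol
        uses 2000; separable synthetic classes converge within ~30).
    lr, batch_size : adaptive-moment optimizer settings.
    conv_channels : output channels of the two convolution blocks.
    dense_units : widths of the two hidden dense layers (the first is the
        256-dim intermediate feature layer).
    validation_fraction : held-out fraction for the per-epoch accuracy log.
    seed : RNG seed for init, shuffling and the validation split
        (deterministic end to end).
    """

    def __init__(
        self,
        epochs: int = 30,
        lr: float = 1e-4,
        batch_size: int = 64,
        conv_channels: tuple[int, int] = (16, 32),
        dense_units: tuple[int, int] = (256, 32),
        pool_kernel: int = 3,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.conv_channels = conv_channels
        self.dense_units = dense_units
        self.pool_kernel = pool_kernel
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- model ----------------------------------------------------------------

    def _build(self, n_classes: int, rng: np.random.Generator) -> nn.Sequential:
        c1, c2 = self.conv_channels
        d1, d2 = self.dense_units
        k = self.pool_kernel
        side = FRAME_SIZE
        side = (side - 2) // k  # conv 3x3 valid + pool
        side = (side - 2) // k
        flat = side * side * c2
        return nn.Sequential(
            [
                nn.Conv2D(1, c1, 3, rng),
                nn.Activation("relu"),
                nn.MaxPool(k),
                nn.Conv2D(c1, c2, 3, rng),
                nn.Activation("relu"),
                nn.MaxPool(k),
                nn.Flatten(),
                nn.Dense(flat, d1, rng),
                nn.Activation("relu"),
                nn.Dense(d1, d2, rng),
                nn.Activation("tanh"),
                nn.Dense(d2, n_classes, rng),
            ]
        )

    def fit(self, X, y) -> "MaskClassifier":
        X = _as_stack(X)[..., None]
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training requires at least two classes")
        rng = np.random.default_rng(self.seed)
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)

        # stratified-ish validation split
        n = len(X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n))) if self.validation_fraction > 0 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            raise ValueError("validation fraction leaves no training data")

        model = self._build(len(classes), rng)
        opt = nn.Adam(model, lr=self.lr)
        onehot = np.eye(len(classes))[y_idx]

        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                logits = model.forward(X[batch], train=True)
                loss, grad = nn.softmax_cross_entropy(logits, onehot[batch])
                model.backward(grad)
                opt.step()
                losses.append(loss)
            train_acc = self._accuracy(model, X[train_idx], y_idx[train_idx])
            val_acc = self._accuracy(model, X[val_idx], y_idx[val_idx]) if n_val else np.nan
            history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": train_acc,
                 "val_accuracy": val_acc}
            )
        self.model_ = model
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = X[0].size
        return self

    @staticmethod
    def _accuracy(model: nn.Sequential, X: np.ndarray, y_idx: np.ndarray, chunk: int = 256) -> float:
        if len(X) == 0:
            return np.nan
        correct = 0
        for start in range(0, len(X), chunk):
            logits = model.forward(X[start : start + chunk])
            correct += int((logits.argmax(axis=1) == y_idx[start : start + chunk]).sum())
        return correct / len(X)

    def final_accuracy(self, last: int = 10) -> dict[str, float]:
        """Mean train/validation accuracy over the last ``last`` epochs."""
        check_is_fitted(self, "model_")
        tail = self.history_.tail(last)
        return {
            "train": float(tail["train_accuracy"].mean()),
            "validation": float(tail["val_accuracy"].mean()),
        }

    # -- inference ------------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """The pre-softmax feature vectors F (one row per mask)."""
        check_is_fitted(self, "model_")
        X = _as_stack(X)[..., None]
        out = [self.model_.forward(X[s : s + 256]) for s in range(0, len(X), 256)]
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def transform(self, X, layer: str = "feature3") -> np.ndarray:
        """Feature extraction: 'feature3' -> F, 'intermediate256' -> the
        256-dim dense activations."""
        check_is_fitted(self, "model_")
        if layer == "feature3":
            return self.decision_function(X)
        if layer == "intermediate256":
            X = _as_stack(X)[..., None]
            # up to and including the relu after the first dense layer
            upto = 9
            out = [self.model_.forward(X[s : s + 256], upto=upto) for s in range(0, len(X), 256)]
            return np.concatenate(out)
        raise ValueError(f"unknown layer {layer!r}")

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        state = self.model_.state_dict()
        np.savez_compressed(
            path,
            classes=self.classes_,
            params=np.array(self.get_params(), dtype=object),
            **{f"w_{k}": v for k, v in state.items()},
        )

    @classmethod
    def load(cls, path) -> "MaskClassifier":
        data = np.load(path, allow_pickle=True)
        est = cls(**data["params"].item())
        rng = np.random.default_rng(est.seed)
        est.classes_ = data["classes"]
        est.model_ = est._build(len(est.classes_), rng)
        est.model_.load_state_dict(
            {k[2:]: data[k] for k in data.files if k.startswith("w_")}
        )
        est.history_ = pd.DataFrame()
        return est
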