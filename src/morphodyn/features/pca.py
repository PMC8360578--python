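"""Principal-component shape space over the classifier features.

The PCA is fitted on per-timeseries time-averaged feature vectors (one point
per cell or simulation run), and any feature vector can then be projected to
(PC1, PC2).  Thin sklearn-style estimator wrapping :class:`sklearn.PCA`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["ShapePCA"]


class ShapePCA(BaseEstimator, TransformerMixin):
    """PCA over feature vectors; ``latencies_`` are the explained-variance
    fractions (they sum to 1 over all components)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "ShapePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 3:
            raise ValueError("PCA needs at least 3 feature vectors")
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("features have zero variance")
        full = PCA(n_components=min(X.shape), svd_solver="full").fit(X)
        self.mean_ = full.mean_
        self.loadings_ = full.components_            # (k, n_features), orthonormal rows
        self.latencies_ = full.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Project feature vectors onto the first ``n_components`` PCs."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_[: self.n_components].T

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "loadings_")
        payload = {
            "mean": self.mean_.tolist(),
            "loadings": self.loadings_.tolist(),
            "latencies": self.latencies_.tolist(),
            "n_components": self.n_components,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapePCA":
        payload = json.loads(Path(path).read_text())
        est = cls(n_components=payload["n_components"])
        est.mean_ = np.asarray(payload["mean"])
        est.loadings_ = np.asarray(payload["loadings"])
        est.latencies_ = np.asarray(payload["latencies"])
        est.n_features_in_ = est.loadings_.shape[1]
        return est
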