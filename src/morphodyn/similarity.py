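"""Similarity scoring of morphologies against reference classes.

A candidate's time-averaged feature vector is compared with the mean feature
vector of each reference class by Euclidean distance in F space.  Low score =
high similarity; the per-class scores play the Score-D / Score-H / Score-K
roles when the references are Dictyostelium, HL-60 and keratocyte data.
Candidates are ranked per class in ascending score with ties broken by
lexicographic candidate id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSet",
    "SimilarityScore",
    "reference_means",
    "similarity_score",
    "score_table",
    "rank_simulations",
    "per_snapshot_classification",
    "mean_feature",
]


@dataclass
class ReferenceSet:
    """class label -> mean feature vector (mean of per-series time averages)."""

    means: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.means = {k: np.asarray(v, dtype=float) for k, v in self.means.items()}
        dims = {v.shape for v in self.means.values()}
        if len(dims) > 1:
            raise ValueError("reference means must share one feature dimension")
        for label, vec in self.means.items():
            if not np.isfinite(vec).all():
                raise ValueError(f"non-finite reference mean for class {label!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.means)


@dataclass
class SimilarityScore:
    candidate: str
    distances: dict[str, float]

    def rank_key(self, label: str) -> float:
        return self.distances[label]


def mean_feature(features: np.ndarray, burn_in_fraction: float = 0.1) -> np.ndarray:
    """Time-averaged feature vector of one series, discarding an initial
    burn-in (default the first 10% of frames)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    start = int(np.floor(burn_in_fraction * len(features)))
    return features[start:].mean(axis=0)


def reference_means(table: pd.DataFrame, class_col: str = "class",
                    series_col: str = "series") -> ReferenceSet:
    """Class means over per-series time-averaged features.

    ``table`` holds one row per frame with feature columns (all numeric
    columns except the grouping ones).
    """
    feat_cols = [c for c in table.columns if c not in (class_col, series_col)
                 and np.issubdtype(table[c].dtype, np.number)]
    if not feat_cols:
        raise ValueError("no numeric feature columns found")
    per_series = table.groupby([class_col, series_col])[feat_cols].mean()
    means = per_series.groupby(level=0).mean()
    if (per_series.groupby(level=0).size() == 0).any() or means.empty:
        raise ValueError("every class needs at least one series")
    return ReferenceSet({str(k): v.to_numpy() for k, v in means.iterrows()})


def similarity_score(candidate_mean: np.ndarray, reference: ReferenceSet,
                     candidate_id: str = "candidate") -> SimilarityScore:
    """Euclidean distance of one candidate mean F to every class mean."""
    vec = np.asarray(candidate_mean, dtype=float)
    dists = {}
    for label, mean in reference.means.items():
        if mean.shape != vec.shape:
            raise ValueError(
                f"feature dimension mismatch: candidate {vec.shape} vs class "
                f"{label!r} {mean.shape}"
            )
        dists[label] = float(np.linalg.norm(vec - mean))
    return SimilarityScore(candidate_id, dists)


def score_table(candidates: dict[str, np.ndarray], reference: ReferenceSet) -> pd.DataFrame:
    """Score many candidates; one row per candidate, one column per class."""
    rows = []
    for cid, vec in candidates.items():
        score = similarity_score(vec, reference, cid)
        rows.append({"candidate": cid, **{f"score_{k}": v for k, v in score.distances.items()}})
    return pd.DataFrame(rows).set_index("candidate")


def rank_simulations(scores: pd.DataFrame, label: str) -> pd.DataFrame:
    """Stable ascending sort by the class score (rank 1 = most similar);
    ties break by candidate id."""
    col = f"score_{label}" if f"score_{label}" in scores.columns else label
    if col not in scores.columns:
        raise KeyError(f"no score column for class {label!r}")
    out = scores.sort_index(kind="stable").sort_values(col, kind="stable")
    out = out.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def per_snapshot_classification(classifier, masks) -> dict[str, float]:
    """Fraction of frames assigned to each class by argmax class probability."""
    if len(masks) == 0:
        raise ValueError("empty mask series")
    predicted = classifier.predict(masks)
    labels = classifier.classes_
    counts = {str(lbl): float((predicted == lbl).mean()) for lbl in labels}
    return counts
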