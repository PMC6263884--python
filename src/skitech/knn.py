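"""Correlation-feature KNN baseline.

Each cycle is summarized by the Pearson correlations of every unordered
channel pair, in lexicographic (i < j) order, plus one appended scalar: the
cycle's original length before resampling, normalized to [0, 1].  For C
channels the feature vector has length C(C-1)/2 + 1 -- 1276 for the full
51-channel tracker set.  Classification is Euclidean k-nearest neighbours
with majority vote; ties are broken by the nearest neighbour's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import ValidationError
from .segmentation import CycleSet

__all__ = ["feature_length", "extract_features", "CorrelationKNN", "KNNResult",
           "knn_fit_predict"]


def feature_length(n_channels: int) -> int:
    """C(C-1)/2 pairwise correlations plus the length scalar."""
    return n_channels * (n_channels - 1) // 2 + 1


def _cycle_correlations(cycle: np.ndarray, iu) -> np.ndarray:
    # Pearson correlations with constant channels mapped to 0 by convention.
    x = cycle - cycle.mean(axis=0)
    norms = np.sqrt((x * x).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    corr = (x.T @ x) / np.outer(safe, safe)
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    return np.clip(corr[iu], -1.0, 1.0)


def extract_features(cs: CycleSet) -> np.ndarray:
    """Feature matrix of shape (n_cycles, C(C-1)/2 + 1).

    The appended scalar is ``orig_len / (2 * target_len)`` clipped to [0, 1],
    a bounded tempo cue available before resampling.
    """
    if cs.n_cycles < 1:
        raise ValidationError("cycle set is empty")
    C = len(cs.channels)
    iu = np.triu_indices(C, k=1)
    feats = np.empty((cs.n_cycles, feature_length(C)), dtype=np.float64)
    lens = cs.provenance["orig_len"].to_numpy(dtype=np.float64)
    for i in range(cs.n_cycles):
        feats[i, :-1] = _cycle_correlations(cs.cycles[i].astype(np.float64), iu)
    feats[:, -1] = np.clip(lens / (2.0 * cs.target_len), 0.0, 1.0)
    return feats


@dataclass
class KNNResult:
    """Fitted nearest-neighbour index plus the training labels."""

    k: int
    train_features: np.ndarray
    train_labels: np.ndarray
    _index: NearestNeighbors

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        dist, idx = self._index.kneighbors(features, n_neighbors=self.k)
        out = np.empty(features.shape[0], dtype=self.train_labels.dtype)
        for r in range(features.shape[0]):
            votes = self.train_labels[idx[r]]
            labels, counts = np.unique(votes, return_counts=True)
            top = labels[counts == counts.max()]
            if len(top) == 1:
                out[r] = top[0]
            else:
                # tie: first neighbour (in distance order) holding a tied label
                out[r] = next(v for v in votes if v in top)
        return out


class CorrelationKNN:
    """Estimator wrapper: ``CorrelationKNN(k).fit(features, labels)``."""

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValidationError("k must be >= 1")
        self.k = k

    def fit(self, train_features: np.ndarray, train_labels: np.ndarray) -> KNNResult:
        train_features = np.asarray(train_features, dtype=np.float64)
        train_labels = np.asarray(train_labels)
        if train_features.shape[0] == 0:
            raise ValidationError("empty training set")
        if self.k > train_features.shape[0]:
            raise ValidationError(f"k={self.k} exceeds training size {train_features.shape[0]}")
        index = NearestNeighbors(n_neighbors=self.k, metric="euclidean")
        index.fit(train_features)
        return KNNResult(self.k, train_features, train_labels, index)


def knn_fit_predict(train_features, train_labels, test_features, k: int = 5) -> np.ndarray:
    """One-shot fit + predict (Euclidean majority vote, nearest-neighbour ties)."""
    return CorrelationKNN(k).fit(train_features, train_labels).predict(test_features)
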