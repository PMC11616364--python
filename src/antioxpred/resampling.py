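"""SMOTE minority oversampling, implemented from first principles.

A synthetic minority point is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``,
``x`` a uniformly chosen minority sample (with replacement) and ``x_nn`` one
of its ``m_neighbors`` nearest minority neighbours by Euclidean distance,
self excluded. Original rows are kept unchanged and first; synthetic rows are
appended until minority/majority reaches ``target_ratio``.

Parent selection is uniform with replacement rather than a fixed per-point
quota so that non-integer amplification factors hit the target count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .errors import InputError
from .io import LabeledDataset


@dataclass
class SmoteConfig:
    m_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0
    mode: str = "fold-safe"   # "paper": balance once before CV; "fold-safe": per training fold

    def __post_init__(self) -> None:
        if self.m_neighbors < 1:
            raise InputError("m_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise InputError("target_ratio must be positive")
        if self.mode not in ("paper", "fold-safe"):
            raise InputError(f"mode must be 'paper' or 'fold-safe', got {self.mode!r}")


class SmoteOversampler(BaseEstimator):
    """Sampler with an imbalanced-learn-style ``fit_resample`` interface."""

    def __init__(self, m_neighbors: int = 5, target_ratio: float = 1.0, seed: int = 0):
        self.m_neighbors = m_neighbors
        self.target_ratio = target_ratio
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InputError("X must be 2-D with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise InputError("SMOTE requires both classes present")
        minority = classes[np.argmin(counts)]
        n_min = int(counts.min())
        n_maj = int(counts.max())

        n_target = int(round(self.target_ratio * n_maj))
        n_syn = n_target - n_min
        if n_syn <= 0:
            return X.copy(), y.copy()
        if n_min <= self.m_neighbors:
            raise InputError(
                f"minority class has {n_min} samples but m_neighbors="
                f"{self.m_neighbors}; use a smaller M"
            )

        X_min = X[y == minority]
        nn = NearestNeighbors(n_neighbors=self.m_neighbors + 1).fit(X_min)
        # column 0 is the point itself (distance 0 ties resolve to self index
        # only up to duplicates; any zero-distance neighbour is an identical
        # point, so interpolation is unaffected)
        neigh_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

        rng = np.random.default_rng(self.seed)
        parents = rng.integers(0, n_min, size=n_syn)
        which = rng.integers(0, self.m_neighbors, size=n_syn)
        u = rng.uniform(0.0, 1.0, size=n_syn)
        x_par = X_min[parents]
        x_nn = X_min[neigh_idx[parents, which]]
        X_syn = x_par + u[:, None] * (x_nn - x_par)

        X_out = np.vstack([X, X_syn])
        y_out = np.concatenate([y, np.full(n_syn, minority, dtype=int)])
        return X_out, y_out


def smote_oversample(dataset: LabeledDataset, config: SmoteConfig) -> LabeledDataset:
    """Rebalance a labelled dataset; synthetic ids are ``syn_0001`` etc."""
    sampler = SmoteOversampler(
        m_neighbors=config.m_neighbors,
        target_ratio=config.target_ratio,
        seed=config.seed,
    )
    X_out, y_out = sampler.fit_resample(dataset.features, dataset.labels)
    n_syn = X_out.shape[0] - dataset.n_samples
    ids = list(dataset.ids) + [f"syn_{i + 1:04d}" for i in range(n_syn)]
    return LabeledDataset(
        ids=ids,
        features=X_out,
        labels=y_out,
        feature_names=list(dataset.feature_names),
    )
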