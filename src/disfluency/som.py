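"""Kohonen self-organising-map baseline feature extractor.

The comparison arm quantises each 21-dimensional band-level frame with a
5 x 5 Kohonen map trained online for 100 epochs at a constant learning
rate of 0.1, with a "bubble" neighbourhood whose Chebyshev radius shrinks
linearly from 3 to 0.  An utterance's 171 frames then become the 171-long
sequence of winning-unit indices (row-major), the feature vector fed to
the classifier.

Frames are z-scored with the training pool's per-band statistics before
training and lookup: the dB bands have very unequal variances and a raw
Euclidean best-matching-unit search would be dominated by the loudest
bands.

The per-frame update loop is compiled with numba; a small pure-python
reference implementation is kept alongside for verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .pca import _levels

__all__ = ["SOMModel", "train_som", "bmu_sequence", "SOMFeatureExtractor"]


@dataclass
class SOMModel:
    """Trained codebook: one weight vector per grid unit (row-major)."""

    weights: np.ndarray          # (n_units, dim)
    grid_shape: tuple[int, int]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_log: np.ndarray     # quantisation error per epoch

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.ravel().tolist(),
            "grid_shape": list(self.grid_shape),
            "dim": int(self.weights.shape[1]),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_log": self.training_log.tolist(),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SOMModel":
        obj = json.loads(text)
        dim = obj["dim"]
        return cls(
            weights=np.asarray(obj["weights"]).reshape(-1, dim),
            grid_shape=tuple(obj["grid_shape"]),
            feature_means=np.asarray(obj["feature_means"]),
            feature_sds=np.asarray(obj["feature_sds"]),
            training_log=np.asarray(obj["training_log"]),
        )


def _grid_coords(grid_shape):
    rows, cols = np.divmod(np.arange(grid_shape[0] * grid_shape[1]),
                           grid_shape[1])
    return rows.astype(np.int64), cols.astype(np.int64)


def _som_step(weights, x, radius, lr, grid_shape):
    """One online update (pure-python reference): find the best-matching
    unit, then move every unit within Chebyshev grid radius toward x."""
    d = np.sum((weights - x) ** 2, axis=1)
    bmu = int(np.argmin(d))
    rows, cols = _grid_coords(grid_shape)
    hood = np.maximum(np.abs(rows - rows[bmu]),
                      np.abs(cols - cols[bmu])) <= radius
    weights[hood] += lr * (x - weights[hood])
    return bmu


@njit(cache=False)
def _som_train_kernel(frames, weights, order, radii, lr, rows, cols):
    n_frames, dim = frames.shape
    n_units = weights.shape[0]
    epochs = radii.shape[0]
    qe = np.empty(epochs)
    for e in range(epochs):
        r = radii[e]
        for t in range(n_frames):
            x = frames[order[e, t]]
            best = 0
            bestd = 1e300
            for u in range(n_units):
                d = 0.0
                for j in range(dim):
                    diff = weights[u, j] - x[j]
                    d += diff * diff
                if d < bestd:
                    bestd = d
                    best = u
            br = rows[best]
            bc = cols[best]
            for u in range(n_units):
                dr = rows[u] - br
                if dr < 0:
                    dr = -dr
                dc = cols[u] - bc
                if dc < 0:
                    dc = -dc
                gd = dr if dr > dc else dc
                if gd <= r:
                    for j in range(dim):
                        weights[u, j] += lr * (x[j] - weights[u, j])
        # quantisation error after this epoch
        s = 0.0
        for t in range(n_frames):
            bestd = 1e300
            for u in range(n_units):
                d = 0.0
                for j in range(dim):
                    diff = weights[u, j] - frames[t, j]
                    d += diff * diff
                if d < bestd:
                    bestd = d
            s += np.sqrt(bestd)
        qe[e] = s / n_frames
    return qe


def _radius_schedule(nb_start: int, epochs: int) -> np.ndarray:
    """Neighbourhood radius shrinking linearly from nb_start to 0."""
    if epochs == 1:
        return np.zeros(1, dtype=np.int64)
    frac = (epochs - 1 - np.arange(epochs)) / (epochs - 1)
    return np.rint(nb_start * frac).astype(np.int64)


def train_som(frames, epochs: int = 100, lr: float = 0.1, nb_start: int = 3,
              seed: int = 0, grid_shape: tuple[int, int] = (5, 5)
              ) -> SOMModel:
    """Train the map on pooled band-level frames (rows, dimension 21).

    Online Kohonen updates with constant learning rate; frame presentation
    order is reshuffled every epoch; reproducible for a fixed seed.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty 2-D array")
    means = frames.mean(axis=0)
    sds = frames.std(axis=0, ddof=1) if frames.shape[0] > 1 else \
        np.ones(frames.shape[1])
    sds = np.where(sds > 0, sds, 1.0)
    scaled = (frames - means) / sds

    rng = np.random.default_rng(int(seed))
    n_units = grid_shape[0] * grid_shape[1]
    lo, hi = scaled.min(axis=0), scaled.max(axis=0)
    weights = rng.uniform(lo, hi, size=(n_units, frames.shape[1]))

    order = np.empty((epochs, scaled.shape[0]), dtype=np.int64)
    for e in range(epochs):
        order[e] = rng.permutation(scaled.shape[0])
    radii = _radius_schedule(nb_start, epochs)
    rows, cols = _grid_coords(grid_shape)
    qe = _som_train_kernel(np.ascontiguousarray(scaled), weights, order,
                           radii, float(lr), rows, cols)
    return SOMModel(weights=weights, grid_shape=grid_shape,
                    feature_means=means, feature_sds=sds, training_log=qe)


def bmu_sequence(sample, model: SOMModel) -> np.ndarray:
    """Winning-unit index per frame (ties break to the lowest index)."""
    X = _levels(sample)
    if X.ndim != 2 or X.shape[1] != model.weights.shape[1]:
        raise ValueError("sample dimensionality does not match the codebook")
    scaled = (X - model.feature_means) / model.feature_sds
    d = ((scaled[:, None, :] - model.weights[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


class SOMFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit trains the map on the pooled frames of
    the given utterance matrices; transform returns one winner-index row
    per utterance."""

    def __init__(self, grid_shape: tuple[int, int] = (5, 5),
                 epochs: int = 100, lr: float = 0.1, nb_start: int = 3,
                 random_state: int = 0):
        self.grid_shape = grid_shape
        self.epochs = epochs
        self.lr = lr
        self.nb_start = nb_start
        self.random_state = random_state

    def fit(self, X, y=None):
        pooled = np.vstack([_levels(s) for s in X])
        self.model_ = train_som(pooled, epochs=self.epochs, lr=self.lr,
                                nb_start=self.nb_start,
                                seed=self.random_state,
                                grid_shape=self.grid_shape)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([bmu_sequence(s, self.model_) for s in X])
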