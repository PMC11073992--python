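"""Group-consensus representations via MDS and kernel-density weighting.

The consensus representation of a target is a weighted average of
participants' feature vectors.  The default (kernel-weighted) estimator:

1. embed participants in the plane by metric MDS on their pairwise
   correlation (or cosine) distances;
2. find the densest coordinate of the embedding with an isotropic Gaussian
   kernel evaluated on a regular grid, using a bandwidth equal to the
   smaller of the two axis ranges;
3. weight each participant by ``max_j d_j - d_i`` where ``d_i`` is the
   Euclidean distance from their coordinate to the densest point (the
   furthest participant gets weight zero);
4. average participants' z-scored patterns with those weights.

Two alternative estimators are provided: the unweighted average, and the
distance-weighted average (the same proximity recoding applied to each
participant's mean distance from all others, no MDS involved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from .similarity import PatternMatrix, similarity_matrix, to_distance, \
    similarity_to_reference

logger = logging.getLogger(__name__)

__all__ = [
    "MDSEmbedding",
    "DensityField",
    "embed_mds",
    "densest_point",
    "proximity_weights",
    "alt_weights",
    "consensus_vector",
    "ConsensusRepresentation",
]


@dataclass
class MDSEmbedding:
    participant_ids: list
    coords: np.ndarray          # (n, 2)
    stress: float
    n_init: int
    max_iter: int
    seed: int


@dataclass
class DensityField:
    grid_x: np.ndarray
    grid_y: np.ndarray
    densities: np.ndarray       # (len(grid_y), len(grid_x)) row-major
    bandwidth: float
    densest_point: np.ndarray   # (2,)
    degenerate: bool = False


def embed_mds(distances: np.ndarray, participant_ids=None,
              n_init: int = 4, max_iter: int = 3000,
              seed: int = 0, eps: float = 1e-6) -> MDSEmbedding:
    """Project participants into the plane with metric (stress-minimizing) MDS."""
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.ndim != 2 or distances.shape[1] != n or n < 3:
        raise ValueError("distances must be a square matrix with n >= 3")
    if not np.allclose(distances, distances.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (distances < 0).any():
        raise ValueError("distances must be nonnegative")
    if participant_ids is None:
        participant_ids = list(range(n))
    if np.allclose(distances, 0.0):
        # degenerate: everyone coincides; skip the solver
        return MDSEmbedding(participant_ids=list(participant_ids),
                            coords=np.zeros((n, 2)), stress=0.0,
                            n_init=n_init, max_iter=max_iter, seed=seed)
    import inspect
    if "metric_mds" in inspect.signature(MDS).parameters:
        mds = MDS(n_components=2, metric="precomputed", metric_mds=True,
                  n_init=n_init, max_iter=max_iter, random_state=seed,
                  init="random", eps=eps, normalized_stress=False)
    else:  # scikit-learn < 1.9
        mds = MDS(n_components=2, dissimilarity="precomputed", metric=True,
                  n_init=n_init, max_iter=max_iter, random_state=seed,
                  eps=eps, normalized_stress=False)
    coords = mds.fit_transform(distances)
    return MDSEmbedding(participant_ids=list(participant_ids), coords=coords,
                        stress=float(mds.stress_), n_init=n_init,
                        max_iter=max_iter, seed=seed)


def densest_point(emb: MDSEmbedding, grid_resolution: int = 100) -> DensityField:
    """Gaussian-kernel densest coordinate of the embedding.

    Density at grid node g is ``sum_i exp(-||g - x_i||^2 / (2 h^2))`` with
    bandwidth ``h`` the smaller of the x- and y-axis ranges.  The argmax is
    taken over a regular ``grid_resolution``-per-axis lattice covering the
    bounding box; ties break at the lowest row-major index.
    """
    coords = emb.coords
    ranges = coords.max(axis=0) - coords.min(axis=0)
    h = float(min(ranges))
    if h <= 0:
        # all points coincide along at least one axis; if fully coincident
        # the densest point is that point and the field is degenerate
        if np.allclose(coords, coords[0]):
            return DensityField(grid_x=np.array([coords[0, 0]]),
                                grid_y=np.array([coords[0, 1]]),
                                densities=np.array([[float(len(coords))]]),
                                bandwidth=0.0, densest_point=coords[0].copy(),
                                degenerate=True)
        h = float(max(ranges))  # colinear cloud: fall back to the other axis
    gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_resolution)
    gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_resolution)
    GX, GY = np.meshgrid(gx, gy)                       # row-major: y rows
    d2 = ((GX[..., None] - coords[:, 0]) ** 2
          + (GY[..., None] - coords[:, 1]) ** 2)
    dens = np.exp(-d2 / (2.0 * h ** 2)).sum(axis=-1)
    flat = int(np.argmax(dens))                        # lowest row-major tie
    iy, ix = np.unravel_index(flat, dens.shape)
    return DensityField(grid_x=gx, grid_y=gy, densities=dens, bandwidth=h,
                        densest_point=np.array([gx[ix], gy[iy]]))


def proximity_weights(emb: MDSEmbedding, densest: np.ndarray) -> np.ndarray:
    """Recode distances-to-densest-point as proximity weights.

    ``w_i = max_j d_j - d_i``; the furthest participant gets weight zero.
    If all distances are equal the weights fall back to uniform (flagged
    via a log message).
    """
    d = np.linalg.norm(emb.coords - np.asarray(densest)[None, :], axis=1)
    w = d.max() - d
    if np.allclose(w, 0.0):
        logger.warning("all participants equidistant from the densest point; "
                       "falling back to uniform weights")
        return np.ones_like(d)
    return w


def alt_weights(distances: np.ndarray, method: str) -> np.ndarray:
    """Alternative consensus weights that bypass the MDS step."""
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if method == "unweighted":
        return np.ones(n)
    if method != "distance_weighted":
        raise ValueError("method must be 'unweighted' or 'distance_weighted'")
    mean_d = (distances.sum(axis=1)) / (n - 1)   # zero diagonal assumed
    w = mean_d.max() - mean_d
    if np.allclose(w, 0.0):
        logger.warning("all mean distances equal; uniform fallback")
        return np.ones(n)
    return w


def consensus_vector(patterns: PatternMatrix, weights: np.ndarray,
                     zscore_rows: bool = True) -> np.ndarray:
    """Weighted mean of participants' (row-z-scored) patterns."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != patterns.n_participants:
        raise ValueError("weights length must equal the participant count")
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    vals = patterns.values
    if zscore_rows:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        bad = (sd.ravel() == 0)
        if bad.any():
            logger.warning("%d zero-variance rows excluded from the consensus",
                           int(bad.sum()))
            weights = np.where(bad, 0.0, weights)
            sd = np.where(sd == 0, 1.0, sd)
        vals = (vals - mu) / sd
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    return (weights[:, None] * vals).sum(axis=0) / total


class ConsensusRepresentation(BaseEstimator):
    """Estimator for a target's group-consensus representation.

    Parameters
    ----------
    method : {'kernel_weighted', 'unweighted', 'distance_weighted'}
        How participants are weighted in the consensus average.
    metric : {'pearson', 'cosine'}
        Pairwise similarity metric used both for the inter-participant
        distances and for the similarity-to-consensus transform.
    grid_resolution : lattice size per axis for the density argmax.
    n_init, max_iter, random_state : MDS settings.

    Attributes
    ----------
    weights_ : participant weights used in the average.
    consensus_ : the consensus feature vector.
    embedding_ : the MDS embedding (kernel_weighted only).
    density_ : the evaluated density field (kernel_weighted only).
    """

    def __init__(self, method="kernel_weighted", metric="pearson",
                 grid_resolution=100, n_init=4, max_iter=3000,
                 random_state=0, exclude_self=True):
        self.method = method
        self.metric = metric
        self.grid_resolution = grid_resolution
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.exclude_self = exclude_self

    def fit(self, patterns: PatternMatrix, y=None):
        if self.method not in ("kernel_weighted", "unweighted",
                               "distance_weighted"):
            raise ValueError(f"unknown method {self.method!r}")
        sim = similarity_matrix(patterns, self.metric)
        dist = to_distance(sim)
        if self.method == "kernel_weighted":
            self.embedding_ = embed_mds(dist, patterns.participant_ids,
                                        n_init=self.n_init,
                                        max_iter=self.max_iter,
                                        seed=self.random_state)
            self.density_ = densest_point(self.embedding_,
                                          self.grid_resolution)
            self.weights_ = proximity_weights(self.embedding_,
                                              self.density_.densest_point)
        else:
            self.weights_ = alt_weights(dist, self.method)
        self.consensus_ = consensus_vector(patterns, self.weights_)
        # z-scored rows retained for leave-one-out transforms
        vals = patterns.values
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        self._zrows = (vals - mu) / np.where(sd == 0, 1.0, sd)
        self._fit_ids = list(patterns.participant_ids)
        self.target_id_ = patterns.target_id
        return self

    def transform(self, patterns: PatternMatrix):
        """Similarity of each participant's pattern to the fitted consensus.

        With ``exclude_self=True`` (default) a participant who contributed
        to the fit is compared against the consensus recomputed with their
        own weight removed, avoiding the self-correlation inflation that
        arises when a pattern is correlated with an average containing it
        (the standard leave-one-out practice for similarity-to-group
        analyses).  Patterns from participants outside the fit are compared
        against the full consensus.
        """
        metric = "cosine" if self.metric == "cosine" else "pearson"
        if not self.exclude_self:
            return similarity_to_reference(patterns, self.consensus_, metric)
        w = self.weights_
        total = w.sum()
        S = (w[:, None] * self._zrows).sum(axis=0)
        idx = {p: k for k, p in enumerate(self._fit_ids)}
        frames = []
        for pid, vec in zip(patterns.participant_ids, patterns.values):
            k = idx.get(pid)
            if k is None or total - w[k] <= 0:
                ref = self.consensus_
            else:
                ref = (S - w[k] * self._zrows[k]) / (total - w[k])
            sub = PatternMatrix(vec[None, :], [pid], patterns.target_id,
                                space=patterns.space)
            frames.append(similarity_to_reference(sub, ref, metric))
        return pd.concat(frames, ignore_index=True)

    def fit_transform(self, patterns: PatternMatrix, y=None):
        return self.fit(patterns).transform(patterns)
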