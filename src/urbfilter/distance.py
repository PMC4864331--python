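"""Dissimilarity matrices and Gower centering.

Bray-Curtis is the community-structure dissimilarity; univariate responses
(richness, evenness) use Euclidean distances so that the distance-based
partition reduces exactly to classical ANOVA sums of squares.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix


def _as_matrix(X):
    vals = np.asarray(X, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    ids = [str(i) for i in X.index] if hasattr(X, "index") else None
    return vals, ids


def bray_curtis(X, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the rows of ``X``.

    ``D[j,k] = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik)``.  A pair of
    all-zero rows is assigned distance 0 by convention (with a warning),
    since the formula is 0/0 there.
    """
    vals, inferred = _as_matrix(X)
    if np.any(vals < 0):
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    with np.errstate(invalid="ignore"):
        cond = pdist(vals, metric="braycurtis")
    if np.any(np.isnan(cond)):
        warnings.warn(
            "all-zero cell pairs found; their Bray-Curtis distance is set to 0",
            stacklevel=2,
        )
        cond = np.nan_to_num(cond, nan=0.0)
    return DistanceMatrix(squareform(cond), ids=ids or inferred)


def euclidean(X, ids=None) -> DistanceMatrix:
    """Euclidean distances between rows (or scalar values) of ``X``."""
    vals, inferred = _as_matrix(X)
    return DistanceMatrix(squareform(pdist(vals, metric="euclidean")), ids=ids or inferred)


def gower_center(D) -> np.ndarray:
    """Gower-center a distance matrix into an inner-product matrix G.

    ``G = (I - 11'/n)(-D^2/2)(I - 11'/n)``.  Its trace equals the total sum
    of squared deviations from the multivariate centroid, which is what the
    distance-based ANOVA partitions.
    """
    Dv = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if Dv.ndim != 2 or Dv.shape[0] != Dv.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.all(np.isfinite(Dv)):
        raise ValueError("distance matrix contains non-finite entries")
    A = -0.5 * Dv ** 2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = A - row - col + A.mean()
    return (G + G.T) / 2.0
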