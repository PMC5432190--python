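"""Distances and summary statistics on registered trees.

Registered trees are points of one orthant of tree space, i.e. ordinary
vectors in R^m, so the natural dissimilarity is the squared Euclidean form
s(x_i, x_j) = (z_i - z_j)'(z_i - z_j).  Clustering and ordination operate on
its square root — the Euclidean distance — so that Ward's objective and the
classical-MDS Gram construction B = -1/2 H S^2 H are both textbook-exact.

Also defined here: the tree mean (coordinate-wise average edge profile) and
the tree variance, the mean squared deviation about that mean.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .registration import TreeSetMatrix

__all__ = [
    "dissimilarity",
    "euclidean_distance",
    "distance_matrix",
    "tree_mean",
    "tree_variance",
]


def _as_matrix(Z) -> np.ndarray:
    if isinstance(Z, TreeSetMatrix):
        Z = Z.Z
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    return Z


def dissimilarity(z_i, z_j) -> float:
    """Squared Euclidean dissimilarity between two registered vectors."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape:
        raise ValueError(f"vector length mismatch: {z_i.shape} vs {z_j.shape}")
    d = z_i - z_j
    return float(d @ d)


def euclidean_distance(z_i, z_j) -> float:
    """Euclidean distance (square root of :func:`dissimilarity`)."""
    return float(np.sqrt(dissimilarity(z_i, z_j)))


def distance_matrix(Z, squared: bool = False) -> np.ndarray:
    """All pairwise distances between registered trees.

    Parameters
    ----------
    Z : TreeSetMatrix or (n, m) array
    squared : bool
        Return the squared dissimilarity instead of the Euclidean distance.
    """
    Z = _as_matrix(Z)
    if Z.shape[0] < 2:
        raise ValueError("distance_matrix requires at least two trees")
    metric = "sqeuclidean" if squared else "euclidean"
    return squareform(pdist(Z, metric=metric))


def tree_mean(Z) -> np.ndarray:
    """Tree average mu = (1/n) sum z_i, an edge profile over the reference."""
    Z = _as_matrix(Z)
    if Z.shape[0] == 0:
        raise ValueError("tree_mean requires at least one tree")
    return Z.mean(axis=0)


def tree_variance(Z) -> float:
    """Tree variance sigma^2 = (1/n) sum (z_i - mu)'(z_i - mu) (population form)."""
    Z = _as_matrix(Z)
    mu = tree_mean(Z)
    dev = Z - mu
    return float(np.einsum("ij,ij->", dev, dev) / Z.shape[0])
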