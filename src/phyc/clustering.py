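"""Ward clustering of registered trees and gap-statistic model selection.

Registered trees are Euclidean vectors, so Ward's minimum-variance criterion
applies directly (scipy's ``linkage(..., method="ward")``, the ward.D2
squared-distance update).  The number of clusters is chosen automatically by
the gap statistic: the observed within-cluster dispersion curve log W_k is
compared against its expectation under a null of no cluster structure
(uniform over the per-coordinate range of the data), and the smallest k
satisfying Tibshirani's one-standard-error rule
gap(k) >= gap(k+1) - s_{k+1} is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .registration import TreeSetMatrix
from .treespace import _as_matrix

__all__ = [
    "ClusterResult",
    "ward_linkage",
    "ward_cluster",
    "gap_statistic",
    "gap_select_k",
    "cluster_trees",
    "TreeClusterer",
]


@dataclass
class ClusterResult:
    """Outcome of clustering one registered cohort."""

    labels: np.ndarray  # cluster ids 1..K, aligned with the input rows
    n_clusters: int
    linkage: np.ndarray  # scipy linkage matrix (merge history)
    gap_trace: pd.DataFrame | None  # per-k gap value and simulation SE, if selected
    random_state: int | None = None

    @property
    def K(self) -> int:
        return self.n_clusters


def ward_linkage(Z) -> np.ndarray:
    """Ward merge history for registered vectors (rows of Z)."""
    return linkage(_as_matrix(Z), method="ward")


def ward_cluster(S, K: int) -> np.ndarray:
    """Cut a Ward dendrogram built from a distance matrix into K groups.

    ``S`` may be a square symmetric Euclidean distance matrix, a condensed
    distance vector, or a :class:`TreeSetMatrix` / (n, m) data matrix (then
    distances are Euclidean row distances).  Labels are 1..K.
    """
    S = S.Z if isinstance(S, TreeSetMatrix) else np.asarray(S, dtype=float)
    if S.ndim == 2 and S.shape[0] == S.shape[1] and np.allclose(S, S.T) and np.allclose(np.diag(S), 0):
        n = S.shape[0]
        lk = linkage(squareform(S, checks=False), method="ward")
    elif S.ndim == 1:
        lk = linkage(S, method="ward")
        n = int((1 + np.sqrt(1 + 8 * len(S))) / 2)
    else:
        n = S.shape[0]
        lk = linkage(S, method="ward")
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside 1..{n}")
    return fcluster(lk, t=K, criterion="maxclust")


def _within_dispersion(Z: np.ndarray, labels: np.ndarray) -> float:
    """W_k: summed within-cluster sum of squared deviations from centroids."""
    W = 0.0
    for lab in np.unique(labels):
        block = Z[labels == lab]
        W += float(((block - block.mean(axis=0)) ** 2).sum())
    return W


def gap_statistic(
    Z,
    k_max: int | None = None,
    n_boot: int = 100,
    random_state: int | None = None,
) -> pd.DataFrame:
    """Gap curve gap(k) = E*[log W*_k] - log W_k for k = 1..k_max.

    The reference distribution draws each coordinate uniformly over its
    observed range; reference datasets are clustered with the same Ward
    procedure.  Returns a DataFrame with columns ``k, log_w, gap, se``.
    """
    Z = _as_matrix(Z)
    n = Z.shape[0]
    if k_max is None:
        k_max = min(n - 1, 10)
    if not 1 <= k_max < n:
        raise ValueError(f"k_max={k_max} outside 1..{n - 1}")
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(random_state)
    ks = np.arange(1, k_max + 1)

    def log_w_curve(data: np.ndarray) -> np.ndarray:
        lk = linkage(data, method="ward")
        out = np.empty(len(ks))
        for i, k in enumerate(ks):
            labels = fcluster(lk, t=k, criterion="maxclust") if k > 1 else np.ones(n, int)
            out[i] = np.log(max(_within_dispersion(data, labels), 1e-300))
        return out

    log_w = log_w_curve(Z)
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    log_w_star = np.empty((n_boot, len(ks)))
    for b in range(n_boot):
        ref = rng.uniform(lo, hi, size=Z.shape)
        log_w_star[b] = log_w_curve(ref)
    gap = log_w_star.mean(axis=0) - log_w
    se = log_w_star.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_boot)
    return pd.DataFrame({"k": ks, "log_w": log_w, "gap": gap, "se": se})


def gap_select_k(
    Z,
    k_max: int | None = None,
    n_boot: int = 100,
    random_state: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose K: smallest k with gap(k) >= gap(k+1) - se(k+1) (1-SE rule)."""
    Z = _as_matrix(Z)
    if np.allclose(Z, Z[0]):
        warnings.warn("all registered trees are identical; returning K=1")
        trace = pd.DataFrame({"k": [1], "log_w": [-np.inf], "gap": [0.0], "se": [0.0]})
        return 1, trace
    trace = gap_statistic(Z, k_max=k_max, n_boot=n_boot, random_state=random_state)
    gap, se = trace["gap"].to_numpy(), trace["se"].to_numpy()
    for i in range(len(gap) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(trace["k"].iloc[i]), trace
    return int(trace["k"].iloc[-1]), trace


def cluster_trees(
    Z,
    K: int | None = None,
    k_max: int | None = None,
    n_boot: int = 100,
    random_state: int | None = None,
) -> ClusterResult:
    """Cluster a registered cohort; if K is None it is gap-selected."""
    Zm = _as_matrix(Z)
    trace = None
    if K is None:
        K, trace = gap_select_k(
            Zm, k_max=k_max, n_boot=n_boot, random_state=random_state
        )
    lk = ward_linkage(Zm)
    labels = fcluster(lk, t=K, criterion="maxclust") if K > 1 else np.ones(len(Zm), int)
    return ClusterResult(
        labels=labels,
        n_clusters=int(K),
        linkage=lk,
        gap_trace=trace,
        random_state=random_state,
    )


class TreeClusterer(ClusterMixin, BaseEstimator):
    """Ward clustering with gap-statistic selection, scikit-learn style.

    ``fit(X)`` expects the registered matrix produced by
    :class:`~phyc.registration.TreeRegistration` (any (n, m) array works).

    Parameters
    ----------
    n_clusters : int, optional
        Fixed number of clusters; if None the gap statistic chooses it.
    k_max : int, optional
        Largest candidate K for the gap statistic (default min(n-1, 10)).
    n_boot : int, default 100
        Reference datasets per gap evaluation.
    random_state : int, optional
        Seed for the reference draws.

    Attributes
    ----------
    labels_ : ndarray of cluster ids 1..K
    n_clusters_ : int
    linkage_ : ndarray, scipy merge history
    gap_trace_ : DataFrame or None
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int | None = None,
        n_boot: int = 100,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        result = cluster_trees(
            X,
            K=self.n_clusters,
            k_max=self.k_max,
            n_boot=self.n_boot,
            random_state=self.random_state,
        )
        self.labels_ = result.labels
        self.n_clusters_ = result.n_clusters
        self.linkage_ = result.linkage
        self.gap_trace_ = result.gap_trace
        return self
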