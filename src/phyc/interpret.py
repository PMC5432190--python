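"""Cluster interpretation: classical MDS and sub-clonal diversity curves.

Classical (Torgerson) MDS embeds the registered cohort in a low-dimensional
Euclidean space for visual comparison: the distance matrix S is element-wise
squared, double-centered into B = -1/2 H S^2 H with H = I - (1/n) 11', and
B's top eigenpairs give coordinates X = U L^{1/2}.  Because registered trees
already live in Euclidean space, B is positive semi-definite up to rounding
and a full-rank embedding reproduces every pairwise distance.

The sub-clonal diversity curve is a lineage-through-time-style step function
for a single tree: y(x) = number of clones present (normal cell included)
once a fraction x of the tree's SSNVs has accumulated.  A clone is born when
the full path from the root down to its node has accumulated, so y(0..) = 1
(only the normal cell), the jump to y = 2 happens at the trunk fraction, and
y(1) = 1 + number of sub-clonal nodes.  An upright curve means sub-clones
appeared after few additional SSNVs; long horizontal runs mean each
sub-clone acquired a large share.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .registration import RegisteredTree, ReferenceTree
from .trees import BinaryClonalTree, ClonalTree

__all__ = [
    "MdsEmbedding",
    "DiversityCurve",
    "ClusterDiversitySummary",
    "cmds_embed",
    "ClassicalMDS",
    "diversity_curve",
    "cluster_diversity_summary",
    "plot_embedding",
    "plot_diversity",
]


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MdsEmbedding:
    """Low-dimensional coordinates from classical MDS."""

    coordinates: np.ndarray  # (n, dim), column means zero
    eigenvalues: np.ndarray  # all n eigenvalues of B, descending
    goodness: float  # fraction of positive-eigenvalue mass in the kept axes

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]


def cmds_embed(S, dim: int = 2) -> MdsEmbedding:
    """Classical MDS of a symmetric zero-diagonal distance matrix.

    Negative eigenvalues of the doubly-centered Gram matrix (numerical noise,
    or genuinely non-Euclidean input) are clamped to zero and their axes
    dropped; if fewer than ``dim`` positive eigenvalues exist the remaining
    coordinates are zero-padded with a warning.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be a square distance matrix")
    if not np.allclose(S, S.T):
        raise ValueError("S must be symmetric")
    if not np.allclose(np.diag(S), 0.0):
        raise ValueError("S must have a zero diagonal")
    n = S.shape[0]
    if not 1 <= dim <= n - 1:
        raise ValueError(f"dim={dim} outside 1..{n - 1}")
    H = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * H @ (S**2) @ H
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    # eigenvalues within rounding noise of zero carry no geometry; zero them
    # so sqrt does not inject ~1e-8 artifacts into the coordinates
    pos[pos <= 1e-12 * max(pos.max(), 1.0)] = 0.0
    n_pos = int((pos > 0).sum())
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding the remaining "
            f"{dim - n_pos} coordinates with zeros"
        )
    coords = vecs[:, :dim] * np.sqrt(pos[:dim])
    # deterministic axis signs: largest-magnitude loading is positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    total_pos = float(pos.sum())
    goodness = float(pos[:dim].sum() / total_pos) if total_pos > 0 else 1.0
    return MdsEmbedding(coordinates=coords, eigenvalues=vals, goodness=goodness)


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical MDS as a scikit-learn-style transformer on precomputed distances.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimension (2 suffices for visual comparison of cohorts).

    Attributes
    ----------
    embedding_ : ndarray (n, n_components)
    eigenvalues_ : ndarray, all eigenvalues descending
    goodness_ : float, positive-eigenvalue mass captured
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        result = cmds_embed(X, dim=self.n_components)
        self.embedding_ = result.coordinates
        self.eigenvalues_ = result.eigenvalues
        self.goodness_ = result.goodness
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.embedding_

    def transform(self, X):
        # CMDS has no out-of-sample map; transform re-fits on the given matrix.
        return cmds_embed(X, dim=self.n_components).coordinates


# ---------------------------------------------------------------------------
# Sub-clonal diversity curves
# ---------------------------------------------------------------------------

@dataclass
class DiversityCurve:
    """Right-continuous step function: clone count vs accumulated-SSNV fraction.

    ``breakpoints`` holds the jump positions as (x, y-after-jump) pairs in
    ascending x; between jumps the curve is constant and y(x < first jump) = 1.
    """

    breakpoints: list[tuple[float, int]]
    label: str = ""

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.breakpoints]
        ys = [y for _, y in self.breakpoints]
        if xs != sorted(xs):
            raise ValueError("breakpoints must be in ascending x order")
        if any(b >= a for b, a in zip(ys, ys[1:])):
            raise ValueError("clone counts must strictly increase across jumps")

    @property
    def trunk_fraction(self) -> float:
        """x of the 1 -> 2 jump: the founder clone's share of SSNVs."""
        return self.breakpoints[0][0]

    @property
    def n_clones_total(self) -> int:
        return self.breakpoints[-1][1]

    def y_at(self, x: float) -> int:
        """Clone count once fraction ``x`` of SSNVs has accumulated.

        A small absolute tolerance (1e-9) absorbs floating-point noise in the
        cumulative root distances, so querying exactly at a jump is safe.
        """
        xs = [bx for bx, _ in self.breakpoints]
        i = bisect_right(xs, x + 1e-9)
        return self.breakpoints[i - 1][1] if i else 1

    def step_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays including the (0, 1) baseline, for step plotting."""
        xs = [0.0] + [x for x, _ in self.breakpoints] + [1.0]
        ys = [1] + [y for _, y in self.breakpoints] + [self.breakpoints[-1][1]]
        return np.asarray(xs), np.asarray(ys)


def _node_distances_from_tree(tree: ClonalTree) -> list[float]:
    total = tree.total_length
    if abs(total - 1.0) < 1e-9:
        total = 1.0  # snap away rounding noise so jumps sit at exact fractions
    if not np.isclose(total, 1.0):
        warnings.warn(
            f"tree {tree.label!r} edge lengths sum to {total:g}, not 1; "
            "normalizing internally"
        )
    counted = (
        tree.original_nodes() if isinstance(tree, BinaryClonalTree) else tree.node_ids
    )
    return [
        tree.root_distance_of(n) / total for n in counted if n != tree.root_id
    ]


def _node_distances_from_vector(z: np.ndarray, ref: ReferenceTree) -> list[float]:
    total = float(z.sum())
    if total <= 0:
        raise ValueError("registered vector has zero total length")
    if abs(total - 1.0) < 1e-9:
        total = 1.0  # snap away rounding noise so jumps sit at exact fractions
    if not np.isclose(total, 1.0):
        warnings.warn(f"registered vector sums to {total:g}, not 1; normalizing")
    out = []
    for k in range(1, ref.n_edges + 1):
        if z[k - 1] > 0:
            out.append(sum(z[j - 1] for j in ref.path_to_root(k)) / total)
    return out


def diversity_curve(obj, reference: ReferenceTree | None = None, label: str | None = None) -> DiversityCurve:
    """Sub-clonal diversity curve of one tree.

    ``obj`` may be a :class:`~phyc.trees.ClonalTree` (binarized or not; for a
    binarized tree the zero-length spine artifacts are not counted as
    clones), a :class:`~phyc.registration.RegisteredTree`, or a registered
    vector together with its :class:`ReferenceTree`.  Lengths are expected
    normalized; unnormalized input is normalized with a warning.

    Each non-root node becomes a clone at x = its cumulative root distance;
    ties merge into a single jump of the tied multiplicity.
    """
    if isinstance(obj, ClonalTree):
        dists = _node_distances_from_tree(obj)
        name = obj.label
    elif isinstance(obj, RegisteredTree):
        dists = _node_distances_from_vector(obj.z, obj.reference)
        name = obj.label
    else:
        if reference is None:
            raise ValueError("a reference tree is required for vector input")
        dists = _node_distances_from_vector(np.asarray(obj, dtype=float), reference)
        name = ""
    if label is not None:
        name = label
    xs = np.sort(np.asarray(dists))
    breakpoints: list[tuple[float, int]] = []
    y = 1
    for x in xs:
        x = float(min(x, 1.0))
        y += 1
        if breakpoints and np.isclose(breakpoints[-1][0], x):
            breakpoints[-1] = (breakpoints[-1][0], y)
        else:
            breakpoints.append((x, y))
    return DiversityCurve(breakpoints=breakpoints, label=name)


@dataclass
class ClusterDiversitySummary:
    """Per-cluster bundle of diversity curves with first-expansion statistics."""

    curves_by_cluster: dict[int, list[DiversityCurve]]
    trunk_fractions_by_cluster: dict[int, list[float]] = field(default_factory=dict)

    @property
    def median_first_expansion(self) -> dict[int, float]:
        """Per-cluster median of the trunk fraction (the x of the 1->2 jump)."""
        return {
            c: float(np.median(v)) for c, v in self.trunk_fractions_by_cluster.items()
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for cluster, curves in self.curves_by_cluster.items():
            for curve in curves:
                rows.append(
                    {
                        "label": curve.label,
                        "cluster": cluster,
                        "trunk_fraction": curve.trunk_fraction,
                        "n_clones_total": curve.n_clones_total,
                    }
                )
        return pd.DataFrame(rows)


def cluster_diversity_summary(curves: list[DiversityCurve], labels) -> ClusterDiversitySummary:
    """Group diversity curves by cluster label and summarize first expansions."""
    labels = np.asarray(labels)
    if len(curves) != len(labels):
        raise ValueError(
            f"{len(curves)} curves but {len(labels)} cluster labels"
        )
    curves_by: dict[int, list[DiversityCurve]] = {}
    fractions_by: dict[int, list[float]] = {}
    for curve, lab in zip(curves, labels):
        lab = int(lab)
        curves_by.setdefault(lab, []).append(curve)
        fractions_by.setdefault(lab, []).append(curve.trunk_fraction)
    return ClusterDiversitySummary(
        curves_by_cluster=curves_by, trunk_fractions_by_cluster=fractions_by
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_embedding(embedding: MdsEmbedding, labels=None, cluster_labels=None, ax=None):
    """Scatter the 2-D MDS coordinates, colored by cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = embedding.coordinates
    colors = None if cluster_labels is None else np.asarray(cluster_labels)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=colors, cmap="tab10")
    if labels is not None:
        for (x, y), text in zip(xy, labels):
            ax.annotate(str(text), (x, y), fontsize=8, xytext=(3, 3), textcoords="offset points")
    if cluster_labels is not None:
        ax.legend(*sc.legend_elements(), title="cluster", loc="best")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax


def plot_diversity(summary: ClusterDiversitySummary, ax=None):
    """Step-plot all diversity curves, colored by cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cmap = plt.get_cmap("tab10")
    for i, (cluster, curves) in enumerate(sorted(summary.curves_by_cluster.items())):
        color = cmap(i % 10)
        for j, curve in enumerate(curves):
            xs, ys = curve.step_arrays()
            ax.step(
                xs,
                ys,
                where="post",
                color=color,
                label=f"cluster {cluster}" if j == 0 else None,
            )
    ax.set_xlabel("fraction of accumulated SSNVs")
    ax.set_ylabel("number of clones")
    ax.legend(loc="best")
    return ax
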