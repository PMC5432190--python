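"""Registration of clonal trees onto a common reference bifurcated tree.

Registration makes heterogeneous rooted trees comparable: a complete
bifurcated *reference tree* deep enough to hold every tree in the cohort is
built, each observed tree is mapped onto it (deepest sub-trees first, ties
broken by edge length), unoccupied reference edges become zero-length
*degenerated* edges, and edge lengths are normalized by the within-tree SSNV
total.  Every tree then becomes a fixed-length non-negative vector summing
to one, and the whole cohort an n x m matrix that lives in a single orthant
of tree space — i.e. ordinary Euclidean space.

The reference tree of depth D has m = 2(2^D - 1) edges, numbered level by
level: edges 1 and 2 leave the root, and edge k has child edges 2k+1 and
2k+2.  The observed trunk always occupies edge 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .trees import (
    BinaryClonalTree,
    ClonalTree,
    binarize_multifurcations,
    canonical_children,
    depth_profile,
)

__all__ = [
    "ReferenceTree",
    "RegisteredTree",
    "TreeSetMatrix",
    "build_reference",
    "canonical_child_order",
    "register",
    "normalize_lengths",
    "register_set",
    "TreeRegistration",
]


@dataclass(frozen=True)
class ReferenceTree:
    """Complete bifurcated tree of a given depth with level-order edge indices."""

    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("reference depth must be >= 1")

    @property
    def n_edges(self) -> int:
        """m = 2(2^D - 1)."""
        return 2 * (2**self.depth - 1)

    def level_of(self, k: int) -> int:
        """Depth level of edge ``k`` (1-based); root edges are level 1."""
        self._check(k)
        return int(np.floor(np.log2(k + 1)))

    def parent_edge(self, k: int) -> int | None:
        self._check(k)
        return None if k <= 2 else (k - 1) // 2

    def child_edges(self, k: int) -> tuple[int, int] | None:
        self._check(k)
        if self.level_of(k) >= self.depth:
            return None
        return (2 * k + 1, 2 * k + 2)

    def path_to_root(self, k: int) -> list[int]:
        """Edge indices from ``k`` up to (and including) its root edge."""
        path = [k]
        while (p := self.parent_edge(path[-1])) is not None:
            path.append(p)
        return path

    def _check(self, k: int) -> None:
        if not 1 <= k <= self.n_edges:
            raise ValueError(f"edge index {k} outside 1..{self.n_edges}")


@dataclass
class RegisteredTree:
    """A tree encoded as an edge-length vector over the reference tree."""

    z: np.ndarray
    mapped: frozenset[int]  # reference edge indices that received an observed edge
    reference: ReferenceTree
    label: str = ""

    @property
    def degenerate(self) -> frozenset[int]:
        return frozenset(range(1, self.reference.n_edges + 1)) - self.mapped


@dataclass
class TreeSetMatrix:
    """Registered cohort: n trees x m reference edges, rows summing to one."""

    Z: np.ndarray
    labels: list[str]
    reference: ReferenceTree
    mapped_sets: list[frozenset[int]] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return self.Z.shape[0]

    @property
    def edge_names(self) -> list[str]:
        return [f"e{k}" for k in range(1, self.reference.n_edges + 1)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.Z, index=self.labels, columns=self.edge_names)


def build_reference(d_max: int) -> ReferenceTree:
    """Reference tree for a cohort of maximum terminal depth ``d_max``."""
    return ReferenceTree(depth=int(d_max))


def canonical_child_order(tree: ClonalTree, node: str) -> list[str]:
    """Children of ``node`` in mapping order.

    Deepest sub-trees are mapped first; among equal depths the longer
    connecting edge wins; remaining ties fall back to subtree total length,
    canonical-form string, and finally input position, so the order is total
    and registration is a function of the tree alone.
    """
    return canonical_children(tree, node)


def register(tree: BinaryClonalTree, ref: ReferenceTree) -> RegisteredTree:
    """Map a binarized tree onto the reference (lengths not yet normalized).

    The trunk occupies reference edge 1; recursively, a node's canonically
    first child takes the lower-index child slot.  Reference edges that
    receive no observed edge keep length zero (degenerated edges).
    """
    if tree.max_depth() > ref.depth:
        raise ValueError(
            f"tree {tree.label!r} has depth {tree.max_depth()} deeper than the "
            f"reference (depth {ref.depth}); rebuild the reference with a "
            "larger d_max"
        )
    z = np.zeros(ref.n_edges)
    mapped: set[int] = set()

    def place(node: str, slots: tuple[int, int]) -> None:
        kids = canonical_child_order(tree, node)
        for child, k in zip(kids, slots):
            z[k - 1] = tree.edge_length_of[child]
            mapped.add(k)
            child_slots = ref.child_edges(k)
            if tree.children(child):
                place(child, child_slots)  # depth check above guarantees slots

    place(tree.root_id, (1, 2))
    return RegisteredTree(z=z, mapped=frozenset(mapped), reference=ref, label=tree.label)


def normalize_lengths(rt: RegisteredTree) -> RegisteredTree:
    """Divide every edge length by the within-tree total (degenerate edges stay 0)."""
    total = float(rt.z.sum())
    if total <= 0:
        raise ValueError(f"tree {rt.label!r} has zero total edge length")
    if abs(total - 1.0) < 1e-12:  # already normalized: exact idempotence
        return RegisteredTree(
            z=rt.z.copy(), mapped=rt.mapped, reference=rt.reference, label=rt.label
        )
    return RegisteredTree(
        z=rt.z / total, mapped=rt.mapped, reference=rt.reference, label=rt.label
    )


def register_set(
    trees: list[ClonalTree],
    depth: int | None = None,
    normalize: bool = True,
) -> TreeSetMatrix:
    """Binarize, register and normalize a cohort onto one shared reference.

    The reference depth defaults to the cohort maximum terminal depth
    (computed after binarization).  Combining cohorts therefore re-registers
    everything at the union depth.
    """
    if not trees:
        raise ValueError("register_set requires at least one tree")
    binarized: list[BinaryClonalTree] = []
    for i, t in enumerate(trees):
        try:
            binarized.append(binarize_multifurcations(t))
        except Exception as exc:
            raise ValueError(f"tree {t.label or i}: {exc}") from exc
    profiles, d_max = depth_profile(binarized)
    if depth is not None:
        if depth < d_max:
            offender = next(
                p.label or str(i) for i, p in enumerate(profiles) if p.max_depth > depth
            )
            raise ValueError(
                f"requested reference depth {depth} is smaller than the cohort "
                f"maximum depth {d_max} (tree {offender!r} is too deep)"
            )
        d_max = depth
    ref = build_reference(d_max)
    rows, mapped_sets, labels = [], [], []
    for i, bt in enumerate(binarized):
        try:
            rt = register(bt, ref)
            if normalize:
                rt = normalize_lengths(rt)
        except Exception as exc:
            raise ValueError(f"tree {bt.label or i}: {exc}") from exc
        rows.append(rt.z)
        mapped_sets.append(rt.mapped)
        labels.append(bt.label or f"tree{i + 1}")
    return TreeSetMatrix(
        Z=np.vstack(rows), labels=labels, reference=ref, mapped_sets=mapped_sets
    )


class TreeRegistration(TransformerMixin, BaseEstimator):
    """Transformer turning a list of :class:`ClonalTree` into a registered matrix.

    ``fit`` learns the cohort reference depth (or uses ``depth`` if given);
    ``transform`` binarizes, maps and normalizes each tree, returning the
    n x m array whose rows sum to one.  Composes with scikit-learn pipelines
    and with :class:`~phyc.clustering.TreeClusterer`.

    Parameters
    ----------
    depth : int, optional
        Reference depth; default is the maximum terminal depth over the
        trees seen in ``fit``.
    normalize : bool, default True
        Divide each tree's edge lengths by its SSNV total.

    Attributes
    ----------
    d_max_ : int
        Reference depth in use after ``fit``.
    reference_ : ReferenceTree
    n_features_out_ : int
        Number of reference edges m = 2(2^d_max - 1).
    """

    def __init__(self, depth: int | None = None, normalize: bool = True):
        self.depth = depth
        self.normalize = normalize

    def fit(self, X: list[ClonalTree], y=None):
        if not X:
            raise ValueError("TreeRegistration.fit requires at least one tree")
        binarized = [binarize_multifurcations(t) for t in X]
        _, d_max = depth_profile(binarized)
        if self.depth is not None:
            if self.depth < d_max:
                raise ValueError(
                    f"depth={self.depth} is smaller than the cohort maximum "
                    f"depth {d_max}"
                )
            d_max = self.depth
        self.d_max_ = d_max
        self.reference_ = build_reference(d_max)
        self.n_features_out_ = self.reference_.n_edges
        return self

    def transform(self, X: list[ClonalTree]) -> np.ndarray:
        if not hasattr(self, "reference_"):
            raise RuntimeError("TreeRegistration is not fitted yet")
        tsm = register_set(X, depth=self.d_max_, normalize=self.normalize)
        return tsm.Z

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"e{k}" for k in range(1, self.n_features_out_ + 1)], dtype=object
        )
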