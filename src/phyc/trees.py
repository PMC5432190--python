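"""Domain model for cancer sub-clonal evolutionary trees.

A cancer evolutionary tree is rooted: the root represents the normal cell,
its (usually single) child is the founder clone, and every further node is a
sub-clone.  Edge lengths count the somatic single-nucleotide variants (SSNVs)
newly acquired by the child clone, so the edge from the normal cell to the
founder — the *trunk* — carries the founder mutations.

This module provides the :class:`ClonalTree` container, Newick I/O (backed by
dendropy), resolution of multifurcations into strictly binary trees via
zero-length spine edges, depth profiles over a cohort, and a small utility to
binarize variant-allele-frequency (VAF) tables.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "ClonalTree",
    "BinaryClonalTree",
    "DepthProfile",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "binarize_multifurcations",
    "depth_profile",
    "binarize_vaf",
]


class TreeValidationError(ValueError):
    """A tree violates the clonal-tree invariants."""


class NewickParseError(ValueError):
    """A Newick string could not be parsed."""


@dataclass
class ClonalTree:
    """Rooted tree with non-negative edge lengths (SSNV counts).

    Parameters
    ----------
    root_id:
        Identifier of the root node (the normal cell).
    parent_of:
        Mapping child node id -> parent node id.  Insertion order fixes the
        sibling order, which is preserved by I/O and traversals.
    edge_length_of:
        Mapping non-root node id -> length of the edge from its parent
        (number of SSNVs; non-negative real).
    label:
        Free-text sample name.
    """

    root_id: str
    parent_of: dict[str, str]
    edge_length_of: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        nodes = set(self.parent_of) | {self.root_id}
        if self.root_id in self.parent_of:
            raise TreeValidationError("root must not have a parent")
        if len(nodes) < 2:
            raise TreeValidationError("a clonal tree needs at least a root and a founder node")
        for child, parent in self.parent_of.items():
            if parent not in nodes:
                raise TreeValidationError(f"parent {parent!r} of {child!r} is not a node")
        for node, length in self.edge_length_of.items():
            if node not in self.parent_of:
                raise TreeValidationError(f"edge length given for non-edge node {node!r}")
            if length < 0:
                raise TreeValidationError(f"negative edge length {length} on node {node!r}")
        if set(self.edge_length_of) != set(self.parent_of):
            missing = set(self.parent_of) - set(self.edge_length_of)
            raise TreeValidationError(f"missing edge lengths for {sorted(missing)}")
        if self.total_length <= 0:
            raise TreeValidationError("total edge length must be positive")
        # connectivity / acyclicity: every node must reach the root
        for node in self.parent_of:
            seen = set()
            while node != self.root_id:
                if node in seen:
                    raise TreeValidationError("cycle detected")
                seen.add(node)
                node = self.parent_of[node]

    # -- basic accessors --------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [self.root_id, *self.parent_of]

    @property
    def n_nodes(self) -> int:
        return 1 + len(self.parent_of)

    @property
    def total_length(self) -> float:
        return float(sum(self.edge_length_of.values()))

    def children_of(self, node: str) -> list[str]:
        return [c for c, p in self.parent_of.items() if p == node]

    @functools.cached_property
    def _children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.node_ids}
        for child, parent in self.parent_of.items():
            out[parent].append(child)
        return out

    def children(self, node: str) -> list[str]:
        """Children in stored (input) order; cached, treat the tree as immutable."""
        return self._children[node]

    def leaves(self) -> list[str]:
        return [n for n in self.node_ids if not self._children[n]]

    def depth_of(self, node: str) -> int:
        """Number of edges on the path root -> node."""
        d = 0
        while node != self.root_id:
            node = self.parent_of[node]
            d += 1
        return d

    def root_distance_of(self, node: str) -> float:
        """Summed edge length on the path root -> node."""
        x = 0.0
        while node != self.root_id:
            x += self.edge_length_of[node]
            node = self.parent_of[node]
        return x

    @functools.cached_property
    def _height(self) -> dict[str, int]:
        # height = edge count to the deepest descendant leaf
        out: dict[str, int] = {}
        for node in reversed(self._preorder()):
            kids = self._children[node]
            out[node] = 1 + max(out[k] for k in kids) if kids else 0
        return out

    def height_of(self, node: str) -> int:
        return self._height[node]

    @functools.cached_property
    def _subtree_length(self) -> dict[str, float]:
        # total edge length inside the subtree rooted at node, incl. its own edge
        out: dict[str, float] = {}
        for node in reversed(self._preorder()):
            own = self.edge_length_of.get(node, 0.0)
            out[node] = own + sum(out[k] for k in self._children[node])
        return out

    def subtree_length_of(self, node: str) -> float:
        return self._subtree_length[node]

    def _preorder(self) -> list[str]:
        order, stack = [], [self.root_id]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self._children.get(node, self.children_of(node))))
        return order

    def max_depth(self) -> int:
        return max(self.depth_of(leaf) for leaf in self.leaves())

    def is_binary(self) -> bool:
        return all(len(self._children[n]) <= 2 for n in self.node_ids)

    # -- structural comparison -------------------------------------------
    def canonical_form(self, node: str | None = None, *, sig_digits: int = 10) -> str:
        """Label-free canonical string of the subtree at ``node`` (default root).

        Two trees are isomorphic with identical lengths iff their canonical
        forms match; used for round-trip checks and as the final registration
        tie-break.
        """
        if node is None:
            node = self.root_id
        kids = sorted(
            (self.canonical_form(k, sig_digits=sig_digits) for k in self._children[node]),
        )
        inner = f"({','.join(kids)})" if kids else ""
        length = self.edge_length_of.get(node)
        tag = "" if length is None else f":{length:.{sig_digits}g}"
        return f"{inner}{tag}"

    def isomorphic_to(self, other: "ClonalTree") -> bool:
        return self.canonical_form() == other.canonical_form()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ClonalTree(label={self.label!r}, n_nodes={self.n_nodes}, "
            f"total_length={self.total_length:g})"
        )


@dataclass
class BinaryClonalTree(ClonalTree):
    """A :class:`ClonalTree` in which every node has at most two children.

    ``spine_of`` records, for every zero-length internal edge inserted while
    resolving a multifurcation, the original node that multifurcated.
    """

    spine_of: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        super().validate()
        for node in self.node_ids:
            if len(self.children_of(node)) > 2:
                raise TreeValidationError(f"node {node!r} has more than two children")

    def original_nodes(self) -> list[str]:
        """Node ids of the source tree (spine artifacts excluded)."""
        return [n for n in self.node_ids if n not in self.spine_of]


@dataclass(frozen=True)
class DepthProfile:
    """Terminal depths of one tree plus the size of its leaf set."""

    terminal_depths: tuple[int, ...]
    label: str = ""

    @property
    def n_terminal(self) -> int:
        return len(self.terminal_depths)

    @property
    def max_depth(self) -> int:
        return max(self.terminal_depths)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _tree_from_dendropy(dtree: dendropy.Tree, label: str) -> ClonalTree:
    seed = dtree.seed_node
    if seed.edge.length not in (None, 0, 0.0):
        warnings.warn(
            "root branch length in Newick input is not meaningful for clonal "
            "trees (the root is the normal cell); ignoring it",
            stacklevel=3,
        )
    used: set[str] = set()
    names: dict[int, str] = {}
    counter = 0
    for node in dtree.preorder_node_iter():
        raw = None
        if node.taxon is not None and node.taxon.label:
            raw = str(node.taxon.label)
        elif node.label:
            raw = str(node.label)
        if raw is None:
            counter += 1
            raw = f"N{counter}"
        name = raw
        k = 1
        while name in used:
            k += 1
            name = f"{raw}.{k}"
        used.add(name)
        names[id(node)] = name

    parent_of: dict[str, str] = {}
    edge_length_of: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        if node is seed:
            continue
        length = node.edge.length
        length = 0.0 if length is None else float(length)
        if length < 0:
            raise TreeValidationError(
                f"negative branch length {length} on node {names[id(node)]!r}"
            )
        parent_of[names[id(node)]] = names[id(node.parent_node)]
        edge_length_of[names[id(node)]] = length
    return ClonalTree(
        root_id=names[id(seed)],
        parent_of=parent_of,
        edge_length_of=edge_length_of,
        label=label,
    )


def parse_newick(text: str, label: str = "") -> ClonalTree:
    """Parse a single rooted Newick string into a :class:`ClonalTree`.

    Branch lengths are optional (default 0).  Malformed input raises
    :class:`NewickParseError` carrying dendropy's position information;
    negative branch lengths raise :class:`TreeValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    return _tree_from_dendropy(dtree, label)


def parse_newick_list(text: str, labels: list[str] | None = None) -> list[ClonalTree]:
    """Parse multi-tree Newick text (one tree per statement)."""
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    out = []
    for i, dtree in enumerate(dtrees):
        label = labels[i] if labels else f"tree{i + 1}"
        out.append(_tree_from_dendropy(dtree, label))
    return out


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: ClonalTree) -> str:
    """Serialize a :class:`ClonalTree` as a rooted Newick string.

    Zero-length edges are written explicitly as ``:0`` so that degenerate
    edges survive a round trip.
    """

    def render(node: str) -> str:
        kids = tree.children(node)
        inner = f"({','.join(render(k) for k in kids)})" if kids else ""
        if node == tree.root_id:
            return f"{inner}{node}"
        return f"{inner}{node}:{_fmt_len(tree.edge_length_of[node])}"

    root_kids = tree.children(tree.root_id)
    return f"({','.join(render(k) for k in root_kids)}){tree.root_id};"


# ---------------------------------------------------------------------------
# Canonical child order and binarization
# ---------------------------------------------------------------------------

def _child_sort_key(tree: ClonalTree, order_index: dict[str, int]):
    """Sort key for children: deepest subtree first, then longest connecting
    edge, then largest subtree total length, then canonical form (reverse
    lexicographic), then input position.  The first two keys follow the
    registration rule (largest depth, then largest edge length); the rest
    make the order total."""

    def key(child: str):
        canon = tree.canonical_form(child)
        return (
            -(1 + tree.height_of(child)),
            -tree.edge_length_of[child],
            -tree.subtree_length_of(child),
            tuple(-ord(c) for c in canon),
            order_index[child],
        )

    return key


def canonical_children(tree: ClonalTree, node: str) -> list[str]:
    """Children of ``node`` in canonical mapping order (deepest/longest first)."""
    kids = tree.children(node)
    order_index = {c: i for i, c in enumerate(kids)}
    return sorted(kids, key=_child_sort_key(tree, order_index))


def binarize_multifurcations(tree: ClonalTree) -> BinaryClonalTree:
    """Resolve multifurcations into a binary tree with zero-length spine edges.

    At each node the canonically-first child keeps its original edge; the
    remaining children hang off a chain of zero-length internal edges, each
    recorded in ``spine_of``.  The total edge length is conserved exactly and
    no terminal depth decreases.  Binary inputs pass through structurally
    unchanged.
    """
    parent_of: dict[str, str] = {}
    edge_length_of: dict[str, float] = {}
    spine_of: dict[str, str] = {}
    spine_count = 0

    def attach(node: str, parent: str | None) -> None:
        nonlocal spine_count
        if parent is not None:
            parent_of[node] = parent
            edge_length_of[node] = float(tree.edge_length_of[node])
        kids = canonical_children(tree, node)
        holder = node
        while len(kids) > 2:
            first, kids = kids[0], kids[1:]
            attach(first, holder)
            spine_count += 1
            spine = f"__spine{spine_count}"
            parent_of[spine] = holder
            edge_length_of[spine] = 0.0
            spine_of[spine] = node
            holder = spine
        for child in kids:
            attach(child, holder)

    attach(tree.root_id, None)
    return BinaryClonalTree(
        root_id=tree.root_id,
        parent_of=parent_of,
        edge_length_of=edge_length_of,
        label=tree.label,
        spine_of=spine_of,
    )


def depth_profile(trees: list[ClonalTree]) -> tuple[list[DepthProfile], int]:
    """Per-tree terminal depth profiles and the cohort-wide maximum depth.

    The cohort maximum d_max is the depth the shared reference tree must
    have so that every tree in the set can be mapped onto it.
    """
    if not trees:
        raise ValueError("depth_profile requires a non-empty set of trees")
    profiles = [
        DepthProfile(
            terminal_depths=tuple(t.depth_of(leaf) for leaf in t.leaves()),
            label=t.label,
        )
        for t in trees
    ]
    d_max = max(p.max_depth for p in profiles)
    return profiles, d_max


# ---------------------------------------------------------------------------
# VAF utility
# ---------------------------------------------------------------------------

def binarize_vaf(vaf_table, threshold: float = 0.05):
    """Binarize a variants x regions VAF table: 1 where VAF >= threshold.

    Accepts a numpy array or pandas DataFrame (returned as the same type);
    entries must lie in [0, 1].
    """
    values = np.asarray(getattr(vaf_table, "values", vaf_table), dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("VAF entries must lie in [0, 1]")
    binary = (values >= threshold).astype(int)
    if hasattr(vaf_table, "values"):  # pandas DataFrame in, DataFrame out
        import pandas as pd

        return pd.DataFrame(binary, index=vaf_table.index, columns=vaf_table.columns)
    return binary
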