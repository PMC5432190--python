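"""Synthetic cohorts of cancer evolutionary trees with known class labels.

Three benchmark designs probe what the clustering can separate:

* design I   — topology classes only, all edge lengths equal;
* design II  — one topology, three SSNV-accumulation classes (trunk /
  balanced / branch accumulation differ in the trunk's share of SSNVs);
* design III — the product of three polyclonal topologies with the three
  accumulation classes: nine classes in all.

Topology archetypes (monoclonal MC; polyclonal low/middle/high PL/PM/PH;
mutator phenotype MT, a deep caterpillar) are frozen constants.  Within-class
spread is controlled by two small-integer indices, larger meaning more
spread: the *dispersion index* drives a Poisson number of random topology
edits (leaf insertion / deletion / regrafting; index 1 means none), and the
*variance index*
widens the Beta distribution of the trunk's SSNV share around the class
center (0.8 trunk-accumulation, 0.5 balanced, 0.2 branch-accumulation); the
remaining SSNVs spread over branch edges by a symmetric Dirichlet.  SSNV
counts are integers; largest-remainder rounding conserves each tree's total
exactly.  All generator constants live in this module; the edit-operation
set and index scales are this package's own reconstruction of the benchmark
conditions rather than canonical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trees import ClonalTree, parse_newick

__all__ = [
    "SimulationConfig",
    "LabeledTreeSet",
    "TOPOLOGY_CLASSES",
    "ACCUMULATION_CLASSES",
    "DESIGN_CLASSES",
    "base_topology",
    "perturb_topology",
    "assign_edge_lengths",
    "generate_design",
]

# Frozen topology archetypes (Newick). Node counts: MC 2 < PL 4 < PM 6 < PH 10;
# MT is a depth-5 caterpillar.
_ARCHETYPES: dict[str, str] = {
    "MC": "(f:1);",
    "PL": "((a:1,b:1)f:1);",
    "PM": "(((c:1,d:1)a:1,b:1)f:1);",
    "PH": "((((g:1,h:1)c:1,d:1)a:1,(e:1,e2:1)b:1)f:1);",
    "MT": "(((((c4:1)c3:1,l3:1)c2:1,l2:1)c1:1,l1:1)f:1);",
}

TOPOLOGY_CLASSES = tuple(_ARCHETYPES)
ACCUMULATION_CLASSES = ("TR", "BL", "BR")

# Class centers of the trunk's share of SSNVs.
_TRUNK_MEAN = {"TR": 0.8, "BL": 0.5, "BR": 0.2}
# Beta concentration at variance index v: tight at v=1, quartered per step.
_BASE_CONCENTRATION = 100.0
# Symmetric Dirichlet parameter spreading non-trunk mass over branch edges.
_BRANCH_ALPHA = 3.0
# Poisson mean of topology edits at dispersion index d: 0.25 * (d - 1).
# Index 1 is the exact archetype (no edits), the strongest-separation setting.
_EDIT_RATE_STEP = 0.25

DESIGN_CLASSES: dict[str, tuple[str, ...]] = {
    # Simulation I compares the four manually built topology classes.
    "I": ("MC", "PL", "PH", "MT"),
    "II": ACCUMULATION_CLASSES,
    "III": tuple(
        f"{topo}-{acc}" for topo in ("PL", "PM", "PH") for acc in ACCUMULATION_CLASSES
    ),
}
# Single topology carrying the length classes of design II.
_DESIGN_II_TOPOLOGY = "PM"


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one simulated cohort."""

    design: str = "III"
    classes: tuple[str, ...] | None = None  # default: the design's class list
    trees_per_class: int = 10
    dispersion_index: int = 1
    variance_index: int = 1
    total_ssnv_range: tuple[int, int] = (50, 200)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGN_CLASSES:
            raise ValueError(f"unknown design {self.design!r}; use I, II or III")
        if self.trees_per_class < 1:
            raise ValueError("trees_per_class must be >= 1")
        if self.dispersion_index < 1 or self.variance_index < 1:
            raise ValueError("dispersion and variance indices start at 1")
        lo, hi = self.total_ssnv_range
        if not 1 <= lo <= hi:
            raise ValueError("total_ssnv_range must be a non-empty positive interval")
        for cls in self.resolved_classes:
            self._check_class(cls)

    @property
    def resolved_classes(self) -> tuple[str, ...]:
        return self.classes if self.classes is not None else DESIGN_CLASSES[self.design]

    def _check_class(self, cls: str) -> None:
        if self.design == "I":
            ok = cls in TOPOLOGY_CLASSES
        elif self.design == "II":
            ok = cls in ACCUMULATION_CLASSES
        else:
            parts = cls.split("-")
            ok = (
                len(parts) == 2
                and parts[0] in TOPOLOGY_CLASSES
                and parts[1] in ACCUMULATION_CLASSES
            )
        if not ok:
            raise ValueError(f"class {cls!r} is not valid for design {self.design}")


@dataclass
class LabeledTreeSet:
    """Simulated cohort with ground-truth class labels."""

    trees: list[ClonalTree]
    truth: list[str]
    config: SimulationConfig = field(
        default_factory=SimulationConfig
    )

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.truth):
            raise ValueError("one truth label per tree required")


def base_topology(class_name: str) -> ClonalTree:
    """Frozen archetype tree of a topology class (unit edge lengths)."""
    if class_name not in _ARCHETYPES:
        raise ValueError(
            f"unknown topology class {class_name!r}; choose from {TOPOLOGY_CLASSES}"
        )
    return parse_newick(_ARCHETYPES[class_name], label=class_name)


# ---------------------------------------------------------------------------
# Topology perturbation
# ---------------------------------------------------------------------------

class _MutableTree:
    """Editable child-list view of a tree for the random edit operations."""

    def __init__(self, tree: ClonalTree):
        self.root = tree.root_id
        self.parent = dict(tree.parent_of)
        self.length = dict(tree.edge_length_of)
        self.counter = 0

    def nodes(self) -> list[str]:
        return [self.root, *self.parent]

    def leaves(self) -> list[str]:
        parents = set(self.parent.values())
        return [n for n in self.parent if n not in parents]

    def insert_leaf(self, under: str) -> None:
        self.counter += 1
        new = f"x{self.counter}"
        while new in self.parent or new == self.root:
            self.counter += 1
            new = f"x{self.counter}"
        self.parent[new] = under
        self.length[new] = 1.0

    def delete_leaf(self, leaf: str) -> None:
        del self.parent[leaf]
        del self.length[leaf]

    def regraft_leaf(self, leaf: str, onto: str) -> None:
        self.parent[leaf] = onto

    def freeze(self, label: str) -> ClonalTree:
        # preorder insertion keeps sibling order deterministic
        children: dict[str, list[str]] = {}
        for child, parent in self.parent.items():
            children.setdefault(parent, []).append(child)
        parent_of: dict[str, str] = {}
        stack = list(reversed(children.get(self.root, [])))
        while stack:
            node = stack.pop()
            parent_of[node] = self.parent[node]
            stack.extend(reversed(children.get(node, [])))
        return ClonalTree(
            root_id=self.root,
            parent_of=parent_of,
            edge_length_of={n: self.length[n] for n in parent_of},
            label=label,
        )


def perturb_topology(
    base: ClonalTree,
    dispersion_index: int,
    seed: int | np.random.Generator | None = None,
) -> ClonalTree:
    """Apply a Poisson number of random leaf edits to an archetype.

    The edit count is Poisson with mean 0.25 * (dispersion_index - 1), so
    index 1 returns the archetype unchanged; each edit picks uniformly among
    the feasible operations: insert a unit leaf under a random non-root
    node, delete a random deletable leaf (keeping at least two nodes and
    never orphaning the trunk), or regraft a leaf under another non-root
    node.  Deterministic for a fixed seed.
    """
    if dispersion_index < 1:
        raise ValueError("dispersion_index must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lam = _EDIT_RATE_STEP * (dispersion_index - 1)
    n_edits = int(rng.poisson(lam))
    if n_edits == 0:
        return base
    mt = _MutableTree(base)
    for _ in range(n_edits):
        ops = []
        non_root = sorted(mt.parent)
        leaves = sorted(mt.leaves())
        deletable = [
            lf
            for lf in leaves
            if len(mt.parent) > 2 and mt.parent[lf] != mt.root
        ]
        regraftable = [
            (lf, target)
            for lf in leaves
            for target in non_root
            if target != lf and target != mt.parent[lf]
        ]
        ops.append("insert")
        if deletable:
            ops.append("delete")
        if regraftable:
            ops.append("regraft")
        op = ops[rng.integers(len(ops))]
        if op == "insert":
            mt.insert_leaf(non_root[rng.integers(len(non_root))])
        elif op == "delete":
            mt.delete_leaf(deletable[rng.integers(len(deletable))])
        else:
            leaf, target = regraftable[rng.integers(len(regraftable))]
            mt.regraft_leaf(leaf, target)
    return mt.freeze(base.label)


# ---------------------------------------------------------------------------
# Edge-length assignment
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Round ``weights * total`` to integers summing exactly to ``total``."""
    raw = weights * total
    floors = np.floor(raw).astype(int)
    short = total - int(floors.sum())
    order = np.argsort(-(raw - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


def assign_edge_lengths(
    tree: ClonalTree,
    class_name: str,
    variance_index: int,
    total_ssnvs: int,
    seed: int | np.random.Generator | None = None,
) -> ClonalTree:
    """Allocate an integer SSNV total over a tree's edges by accumulation class.

    The trunk's share is Beta-distributed around the class center (TR 0.8,
    BL 0.5, BR 0.2) with concentration 100 / 4**(variance_index - 1); the
    rest spreads over the branch edges via a symmetric Dirichlet(3).  The
    returned integer lengths sum to ``total_ssnvs`` exactly.
    """
    if class_name not in _TRUNK_MEAN:
        raise ValueError(
            f"unknown accumulation class {class_name!r}; choose from "
            f"{ACCUMULATION_CLASSES}"
        )
    if variance_index < 1:
        raise ValueError("variance_index must be >= 1")
    edges = list(tree.parent_of)
    if total_ssnvs < len(edges):
        raise ValueError(
            f"total_ssnvs={total_ssnvs} cannot cover {len(edges)} edges"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    trunk_candidates = tree.children(tree.root_id)
    trunk = trunk_candidates[0]
    branch_edges = [e for e in edges if e != trunk]
    mu = _TRUNK_MEAN[class_name]
    conc = _BASE_CONCENTRATION / 4 ** (variance_index - 1)
    p = float(rng.beta(mu * conc, (1.0 - mu) * conc)) if branch_edges else 1.0
    weights = np.empty(len(edges))
    index = {e: i for i, e in enumerate(edges)}
    weights[index[trunk]] = p
    if branch_edges:
        w = rng.dirichlet(np.full(len(branch_edges), _BRANCH_ALPHA))
        for e, wi in zip(branch_edges, w):
            weights[index[e]] = (1.0 - p) * wi
    counts = _largest_remainder(weights, total_ssnvs)
    return ClonalTree(
        root_id=tree.root_id,
        parent_of=dict(tree.parent_of),
        edge_length_of={e: float(counts[index[e]]) for e in edges},
        label=tree.label,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _unit_lengths(tree: ClonalTree) -> ClonalTree:
    return ClonalTree(
        root_id=tree.root_id,
        parent_of=dict(tree.parent_of),
        edge_length_of={e: 1.0 for e in tree.parent_of},
        label=tree.label,
    )


def generate_design(config: SimulationConfig) -> LabeledTreeSet:
    """Generate one labeled cohort for a simulation design.

    Design I perturbs each topology archetype and sets all edge lengths to
    one; design II perturbs the single shared topology and draws class-
    specific length allocations; design III does both per topology-length
    class pair.  Reproducible: the same config (including seed) yields
    byte-identical trees.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.total_ssnv_range
    trees: list[ClonalTree] = []
    truth: list[str] = []
    for cls in config.resolved_classes:
        for i in range(config.trees_per_class):
            label = f"{cls}_{i + 1}"
            if config.design == "I":
                topo = perturb_topology(
                    base_topology(cls), config.dispersion_index, rng
                )
                tree = _unit_lengths(topo)
            else:
                topo_cls, acc_cls = (
                    (_DESIGN_II_TOPOLOGY, cls)
                    if config.design == "II"
                    else tuple(cls.split("-"))
                )
                topo = perturb_topology(
                    base_topology(topo_cls), config.dispersion_index, rng
                )
                total = int(rng.integers(lo, hi + 1))
                total = max(total, len(topo.parent_of))
                tree = assign_edge_lengths(
                    topo, acc_cls, config.variance_index, total, rng
                )
            tree = replace(tree, label=label)
            trees.append(tree)
            truth.append(cls)
    return LabeledTreeSet(trees=trees, truth=truth, config=config)
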