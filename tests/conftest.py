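import numpy as np
import pytest

from phyc import ClonalTree


def make_random_tree(rng: np.random.Generator, max_extra: int = 6, label: str = "") -> ClonalTree:
    """Random clonal tree: trunk plus up to ``max_extra`` randomly attached nodes."""
    parent_of = {"f": "r"}
    lengths = {"f": float(rng.integers(1, 10))}
    nodes = ["f"]
    for i in range(int(rng.integers(0, max_extra + 1))):
        node = f"s{i}"
        parent_of[node] = nodes[int(rng.integers(len(nodes)))]
        lengths[node] = float(rng.integers(0, 10))
        nodes.append(node)
    return ClonalTree(root_id="r", parent_of=parent_of, edge_length_of=lengths, label=label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def random_trees(rng) -> list[ClonalTree]:
    return [make_random_tree(rng, label=f"t{i}") for i in range(20)]
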