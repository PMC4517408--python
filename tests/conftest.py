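import numpy as np
import pytest

from modevol.trees import Node, parse_newick


@pytest.fixture
def species3():
    """Rooted three-taxon species tree ((A,B),C)."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def species4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_topology(rng, leaves):
    """Random binary tree over the given leaf nodes (unit branch lengths)."""
    nodes = list(leaves)
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(Node(children=[a, b]))
    root = nodes[0]
    for n in root.postorder():
        if n.parent is not None:
            n.length = 1.0
    return root
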