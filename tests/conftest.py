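import numpy as np
import pytest

from hybcoal.simulate import default_study_tree, taxon_map_for
from hybcoal.trees import Node, TaxonMap, Tree


@pytest.fixture
def tmap3():
    return TaxonMap({"a": "A", "b": "B", "c": "C"})


@pytest.fixture
def study_tree():
    return default_study_tree()


@pytest.fixture
def study_map():
    return taxon_map_for({"H": 4, "P1": 4, "P2": 4, "O": 2})


def random_topology(labels, rng: np.random.Generator) -> Tree:
    """Uniform-ish random rooted binary topology via sequential joining."""
    nodes = [Node(lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(None, None, [nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return Tree(nodes[0])
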