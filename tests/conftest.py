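import numpy as np
import pytest

from echoconv.phylo import parse_newick
from echoconv.simulate import make_study_fixture


@pytest.fixture(scope="session")
def fixture_tree():
    """The 19-taxon study tree, seed 1 (height ~0.24)."""
    return make_study_fixture(1)


@pytest.fixture(scope="session")
def subtree8(fixture_tree):
    """An 8-taxon subtree spanning all lineage groups (for codon fits)."""
    return fixture_tree.subtree_retaining([
        "Aselliscus_stoliczkanus", "Rhinolophus_sinicus", "Hipposideros_armiger",
        "Taphozous_melanopogon", "Rousettus_leschenaultii", "Pteropus_vampyrus",
        "Tursiops_truncatus", "Homo_sapiens",
    ])


@pytest.fixture
def quartet():
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.07);")


def random_tree(rng: np.random.Generator, n_leaves: int):
    """A random rooted binary tree with uniform(0.01, 0.5) branch lengths."""
    from echoconv.phylo import Node, PhyloTree

    nodes = [Node(label=f"t{i}", length=float(rng.uniform(0.01, 0.5)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(Node(length=float(rng.uniform(0.01, 0.5)), children=[left, right]))
    root = nodes[0]
    root.length = None
    return PhyloTree(root)
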