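import numpy as np
import pytest

from gtdiscord.trees import PhyloTree


@pytest.fixture
def quartet_ab():
    return PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def quartet_ac():
    return PhyloTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")


def random_topology(n_taxa: int, seed: int, labels=None) -> PhyloTree:
    """Random binary unrooted topology by sequential random insertion."""
    rng = np.random.default_rng(seed)
    labels = labels or [f"t{i}" for i in range(n_taxa)]
    # grow as a nested structure rooted at a trifurcation
    tree = [labels[0], labels[1], labels[2]]

    def edges(node, path=()):
        # every child position of every internal list node is an edge
        out = []
        for i, child in enumerate(node):
            out.append(path + (i,))
            if isinstance(child, list):
                out.extend(edges(child, path + (i,)))
        return out

    for leaf in labels[3:]:
        all_edges = edges(tree)
        choice = all_edges[rng.integers(len(all_edges))]
        node = tree
        for step in choice[:-1]:
            node = node[step]
        i = choice[-1]
        node[i] = [node[i], leaf]
    def to_newick(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"
    return PhyloTree.from_newick(to_newick(tree) + ";", rooted=False)
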