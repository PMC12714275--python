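import pytest

import phylodraw as pd


@pytest.fixture
def two_leaf_tree():
    """Smallest valid network: root with leaves a, b."""
    return pd.parse_extended_newick("(a,b);")[0]


@pytest.fixture
def caterpillar():
    """((a,b),c) -- used by the y-averaging examples."""
    return pd.parse_extended_newick("((a,b),c);")[0]


@pytest.fixture
def hybrid_net():
    """One reticulation with two parents; child of the reticulation is b."""
    return pd.parse_extended_newick("((a,(b)#H1),(#H1,c));")[0]


@pytest.fixture
def transfer_net():
    """Same topology with the c-side parent edge marked transfer-acceptor."""
    return pd.parse_extended_newick("((a,(b)#H1),(##H1,c));")[0]


def enumerate_lsa(net, v):
    """Path-enumeration oracle for the lowest stable ancestor.

    Intersects the node sets of all root-to-v paths and returns the node
    of maximal depth among the intersection (excluding v itself).
    """
    import networkx as nx

    g = net.graph()
    paths = list(nx.all_simple_paths(g, net.root, v))
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    common.discard(v)
    # the last common node on any single path is the LSA
    order = {node: i for i, node in enumerate(paths[0])}
    return max(common, key=lambda u: order[u])
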