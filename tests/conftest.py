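import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netkit.graph_core import new_network


@pytest.fixture
def triangle():
    return new_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return new_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    """Center C with 3 leaves."""
    return new_network([("C", "L1"), ("C", "L2"), ("C", "L3")])


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by a single bridge edge C-D."""
    return new_network(
        [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F"), ("C", "D")]
    )


@pytest.fixture
def amyloid_path_fixture():
    """The stated relations: Abeta-AApoAI, AApoAI-ATTR, no direct Abeta-ATTR edge."""
    return new_network([("P05067", "P02647"), ("P02647", "P02766")])


def random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {v: f"N{v:03d}" for v in g.nodes})
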