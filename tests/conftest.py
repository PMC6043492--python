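import networkx as nx
import pytest

from netprox import GeneSet
from netprox.fixtures import make_interactome, plant_disease_module


def str_graph(g: nx.Graph) -> nx.Graph:
    """Relabel integer nodes to the string identifiers the package expects."""
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})


def gs(name, *members) -> GeneSet:
    return GeneSet(name=name, members=frozenset(str(m) for m in members))


@pytest.fixture
def path5() -> nx.Graph:
    """Path graph 1-2-3-4-5."""
    return str_graph(nx.path_graph(range(1, 6)))


@pytest.fixture(scope="session")
def small_interactome() -> nx.Graph:
    """200-node preferential-attachment graph shared across fast tests."""
    return make_interactome(n_nodes=200, attach_m=2, seed=11)


@pytest.fixture(scope="session")
def small_module(small_interactome) -> GeneSet:
    return plant_disease_module(small_interactome, size=20, seed=7)
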