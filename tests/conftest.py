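import networkx as nx
import pytest

from netprio import data_io, synth


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return synth.generate_fixture(synth.FixtureSpec(seed=1), out)


@pytest.fixture(scope="session")
def interactome(bundle) -> data_io.Interactome:
    return data_io.load_interactome(bundle.paths["interactome"])


@pytest.fixture(scope="session")
def drugs(bundle, interactome):
    return data_io.load_drugs(bundle.paths["drugs"], interactome)


@pytest.fixture(scope="session")
def degs(bundle, interactome):
    return data_io.load_degs(bundle.paths["degs"], interactome)


@pytest.fixture(scope="session")
def expression(bundle):
    return data_io.load_expression(
        bundle.paths["expression"], bundle.paths["genes"], bundle.paths["cells"]
    )


@pytest.fixture(scope="session")
def prior(bundle):
    return data_io.load_prior(bundle.paths["prior"])


@pytest.fixture()
def path_graph() -> data_io.Interactome:
    """Path 1-2-3-4-5 wrapped as an Interactome."""
    g = nx.path_graph(range(1, 6))
    return data_io.Interactome(g)


def make_interactome(edges) -> data_io.Interactome:
    g = nx.Graph()
    g.add_edges_from(edges)
    return data_io.Interactome(g)
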