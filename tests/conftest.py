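import numpy as np
import pytest

from circwalk.network import HeterogeneousNetwork, NodeRef
from circwalk.pipeline import run_fixture_pipeline
from circwalk.synthetic import SynthConfig, generate_fixture


def toy_network(edges, kind="miRNA", extra_nodes=()):
    """A HeterogeneousNetwork from a bare edge list, for walk/embedding
    tests where node kinds are irrelevant."""
    net = HeterogeneousNetwork()
    for a, b in edges:
        net.add_node(NodeRef(a, kind))
        net.add_node(NodeRef(b, kind))
        net.graph.add_edge(a, b, relations={"miRNA-mRNA"})
    for n in extra_nodes:
        net.add_node(NodeRef(n, kind))
    return net


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def fixture_bundle(default_config):
    return generate_fixture(default_config)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default planted fixture, shared by
    the slower integration checks."""
    return run_fixture_pipeline(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
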