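import numpy as np
import pytest

from adrnet.network import KPartiteNetwork, ReconciledEntity


def make_net(nodes, edges):
    """Build a small network from (node_id, layer) and (rtype, u, v) lists."""
    net = KPartiteNetwork()
    for nid, layer in nodes:
        net.nodes[nid] = ReconciledEntity(nid, layer, {nid}, {nid}, {"s"})
    for ek in edges:
        net.edges[tuple(ek)] = {"s"}
    return net


@pytest.fixture
def chain_net():
    """Single path d1 - p1 - w1 - a1 through all four layers."""
    return make_net(
        [("d1", "E1"), ("p1", "E2"), ("w1", "E3"), ("a1", "E4")],
        [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")],
    )


@pytest.fixture
def small_net():
    """Two drugs, two proteins, one pathway, two phenotypes; acyclic."""
    return make_net(
        [("d1", "E1"), ("d2", "E1"), ("p1", "E2"), ("p2", "E2"),
         ("w1", "E3"), ("a1", "E4"), ("a2", "E4")],
        [("R1", "d1", "p1"), ("R2", "d2", "p2"),
         ("R4", "p1", "w1"), ("R4", "p2", "w1"),
         ("R5", "w1", "a1"), ("R5", "w1", "a2")],
    )


def random_model(n1, n2, n3, n4, scale=1.0, seed=0, connected=True):
    """Random network + random couplings, for oracle comparisons."""
    from adrnet.synthetic import SyntheticSpec, gen_model, gen_network

    spec = SyntheticSpec(
        layer_sizes=(n1, n2, n3, n4),
        seed=seed,
        ensure_connected=connected,
    )
    net = gen_network(spec)
    return gen_model(net, scale, seed=seed + 1)
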