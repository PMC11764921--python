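import pytest

from sirenet import SignedNetwork, core_channel_scores, core_network_fixture
from sirenet.procomren import WeightedNetwork


@pytest.fixture(scope="session")
def core_net() -> SignedNetwork:
    return core_network_fixture()


@pytest.fixture(scope="session")
def core_scores():
    return core_channel_scores()


def make_weighted_core(
    w_mapk1_rps6ka5: float = 0.73,
    w_rps6ka5_eif4ebp1: float = 0.64,
    w_eif4ebp1_eif4e: float = 0.70,
    w_mapk1_eif4ebp1: float = 0.2,
    w_mtor_eif4ebp1: float = 0.1,
    w_mapk1_mknk1: float = 1.0,
    w_mknk1_eif4e: float = 1.0,
) -> WeightedNetwork:
    """Weighted core network with configurable route weights.

    The six-node core network alone would leave each activated node with a
    single activator, which total probability forces to weight 1; in the full
    network those nodes have further activators, so an auxiliary activator
    node absorbs the remaining activating mass and lets any on-path activating
    weight take a value below 1.
    """
    core = core_network_fixture()
    edges = list(core.edges)
    weights = {
        ("MAPK1", "MKNK1", 1): w_mapk1_mknk1,
        ("MKNK1", "EIF4E", 1): w_mknk1_eif4e,
        ("MAPK1", "RPS6KA5", 1): w_mapk1_rps6ka5,
        ("RPS6KA5", "EIF4EBP1", -1): w_rps6ka5_eif4ebp1,
        ("MAPK1", "EIF4EBP1", -1): w_mapk1_eif4ebp1,
        ("MTOR", "EIF4EBP1", -1): w_mtor_eif4ebp1,
        ("EIF4EBP1", "EIF4E", -1): w_eif4ebp1_eif4e,
    }
    for target, w in (
        ("RPS6KA5", w_mapk1_rps6ka5),
        ("MKNK1", w_mapk1_mknk1),
        ("EIF4E", w_mknk1_eif4e),
    ):
        if w < 1.0:
            edge = ("AUX", target, 1)
            edges.append(edge)
            weights[edge] = 1.0 - w
    nodes = core.nodes | ({"AUX"} if len(edges) > 7 else frozenset())
    host = SignedNetwork(nodes=nodes, edges=tuple(edges))
    return WeightedNetwork(base=host, weights=weights)


@pytest.fixture
def weighted_core() -> WeightedNetwork:
    return make_weighted_core()
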