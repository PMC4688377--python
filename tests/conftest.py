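import pytest

from surrogene.network import PPINetwork
from surrogene.simulate import generate_cohort, generate_network, pick_targets


@pytest.fixture
def path_graph():
    """A - B - C plus isolated D."""
    return PPINetwork.from_edges([("A", "B"), ("B", "C")], extra_nodes=["D"])


@pytest.fixture
def star_graph():
    """Star K1,4: center X, leaves L1..L4."""
    return PPINetwork.from_edges([("X", f"L{i}") for i in range(1, 5)])


@pytest.fixture(scope="session")
def ba_network():
    """The standard synthetic interactome used across tests (N=500, BA m=3)."""
    return generate_network(500, "scale_free", 3, rng_seed=7)


@pytest.fixture(scope="session")
def null_cohort(ba_network):
    """No planted signal: pure background alterations at rate 0.02."""
    return generate_cohort(ba_network, 40, 0.02, [], rng_seed=11)


@pytest.fixture(scope="session")
def planted_cohort(ba_network):
    """Five enrichment-8 targets on the best-connected genes, 40 samples."""
    targets = pick_targets(ba_network, 5, 8.0)
    return generate_cohort(ba_network, 40, 0.02, targets, rng_seed=11)
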