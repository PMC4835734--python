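import numpy as np
import pytest

from sirthresh import GenConfig, Network, configuration_network, fixture, giant_component


@pytest.fixture
def triangle():
    return fixture("cycle", N=3)


@pytest.fixture
def cycle6():
    return fixture("cycle", N=6)


@pytest.fixture
def star4():
    return fixture("star", n=4)


@pytest.fixture
def k4():
    return fixture("clique", N=4)


@pytest.fixture
def regular_4_10():
    return fixture("regular", k=4, N=10)


@pytest.fixture
def path4():
    return Network(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def two_cliques():
    return fixture("two_cliques_bridged", m=5)


@pytest.fixture(scope="session")
def small_config_net():
    """A modest power-law configuration network reused across tests."""
    cfg = GenConfig(N=2000, nu_D=3.0, seed=42)
    return giant_component(configuration_network(cfg))


def cyclic_fixture_suite():
    """Cyclic connected graphs with closed-form or oracle-checkable spectra."""
    return [
        ("triangle", fixture("cycle", N=3)),
        ("cycle6", fixture("cycle", N=6)),
        ("K4", fixture("clique", N=4)),
        ("K5", fixture("clique", N=5)),
        ("regular_4_10", fixture("regular", k=4, N=10)),
        ("regular_6_20", fixture("regular", k=6, N=20)),
        ("two_cliques_5", fixture("two_cliques_bridged", m=5)),
    ]


def random_config_suite(n_networks=20, seed0=100, n_min=60, n_max=150):
    """Small random configuration networks (giant components, cyclic)."""
    nets = []
    rng = np.random.default_rng(seed0)
    i = 0
    while len(nets) < n_networks:
        n = int(rng.integers(n_min, n_max))
        nu = float(rng.uniform(2.2, 3.8))
        cfg = GenConfig(N=n, nu_D=nu, k_min=2, seed=seed0 + i)
        i += 1
        net = giant_component(configuration_network(cfg))
        if net.n_edges >= net.n_nodes:  # cyclic
            nets.append((f"cfg{len(nets)}_N{net.n_nodes}", net))
    return nets
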