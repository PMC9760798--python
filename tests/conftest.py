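import pytest

from boolfate import (
    analytic_fixture,
    default_scheme,
    enumerate_attractors,
    macrophage_fixture,
    parse_network,
    random_nk_network,
)


@pytest.fixture(scope="session")
def toggle_net():
    return analytic_fixture("toggle").network


@pytest.fixture(scope="session")
def ring3_net():
    return analytic_fixture("negation_ring_3").network


@pytest.fixture(scope="session")
def identity3_net():
    return analytic_fixture("identity_3").network


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def macrophage():
    return macrophage_fixture()


@pytest.fixture(scope="session")
def toggle_set(toggle_net):
    return enumerate_attractors(toggle_net, mode="exhaustive")


@pytest.fixture(scope="session")
def toggle_scheme():
    """Maps the toggle net's nodes onto two phenotype markers."""
    from boolfate.phenotype import PhenotypeScheme
    from boolfate.network import parse_expression

    return PhenotypeScheme(
        labels=("M0", "M1", "M2c"),
        conditions={"M1": parse_expression("X"),
                    "M2c": parse_expression("Y")},
        fallback_label="M0",
        outcome_class={"M0": "neutral", "M1": "tumor-eliminating",
                       "M2c": "tumor-promoting"},
    )


def nk_suite(count=100, n_lo=8, n_hi=12, k_max=3, bias=0.5):
    """The deterministic random-network family used by the acceptance suite."""
    span = n_hi - n_lo + 1
    for seed in range(count):
        n = n_lo + seed % span
        k = 1 + seed % k_max
        yield seed, random_nk_network(n=n, k=k, bias=bias, seed=seed)
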