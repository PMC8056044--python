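import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio import SynthConfig, generate_network, generate_pvalues


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 400-gene instance with one planted 50-gene module."""
    return SynthConfig(
        n_genes=400,
        module_sizes=(50,),
        n_risk_signal=30,
        n_endo_signal=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_instance(small_config):
    network, truth = generate_network(small_config)
    risk = generate_pvalues(truth, small_config, "risk")
    endo = generate_pvalues(truth, small_config, "endo")
    return network, truth, risk, endo


@pytest.fixture
def toy_network() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([
        ("g1", "p1", 0.7),
        ("g1", "g2", 0.2),
        ("p1", "p2", 0.9),
        ("g2", "p2", 0.4),
    ])
    return g
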