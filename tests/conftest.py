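"""Shared fixtures: the fixture network and simulated datasets.

Session-scoped so the expensive objects (132-species network, 4-condition
simulations) are built once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from hmlm.network import Edge, Node, SignalingNetwork, generate_fixture_network
from hmlm.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def net():
    return generate_fixture_network(n_species=132, seed=1)


@pytest.fixture(scope="session")
def dataset(net):
    """Default study conditions: 4 x 100 x 132, noise sd 0.015."""
    return generate_dataset(net, SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_clean(net):
    """Noise-free reference run."""
    return generate_dataset(net, SimulationConfig(seed=1, noise_sd=0.0))


@pytest.fixture()
def chain_net():
    """Minimal 3-node directed chain a -> b -> c."""
    nodes = [
        Node("a", "inputs"),
        Node("b", "receptors", "receptor"),
        Node("c", "transcription_factors", "transcription-factor"),
    ]
    edges = [Edge("a", "b", 1, 1.0), Edge("b", "c", 1, 1.0)]
    return SignalingNetwork(nodes, edges)
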