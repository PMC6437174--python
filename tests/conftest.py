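"""Shared fixtures: small deterministic networks and converged states."""

import numpy as np
import pytest

from vasculoscope.hemodynamics import FlowConfig, simulate_hemodynamics
from vasculoscope.network import BoundaryCondition, Node, Segment, VascularNetwork
from vasculoscope.synth import TumorLikeParams, make_bifurcation_tree, make_line, make_tumor_like

#: pressure drop of 100 Pa expressed in mmHg
DP_100PA_MMHG = 100.0 / 133.322387415


@pytest.fixture
def single_vessel():
    """One segment, D = 10 µm, L = 100 µm, 100 Pa drop."""
    return make_line(10.0, 100.0, 1, inlet_pressure=DP_100PA_MMHG, outlet_pressure=0.0)


@pytest.fixture
def y_network():
    """A diverging bifurcation: parent D = 20 µm into daughters 16/12 µm."""
    nodes = [
        Node(0, (0.0, 0.0, 0.0)),
        Node(1, (100.0, 0.0, 0.0)),
        Node(2, (200.0, 50.0, 0.0)),
        Node(3, (200.0, -50.0, 0.0)),
    ]
    segments = [
        Segment(0, 0, 1, 20.0, 100.0),
        Segment(1, 1, 2, 16.0, 120.0),
        Segment(2, 1, 3, 12.0, 120.0),
    ]
    return VascularNetwork(nodes, segments)


@pytest.fixture(scope="session")
def tumor_net():
    return make_tumor_like(TumorLikeParams(seed=7, n_segments=250))


@pytest.fixture(scope="session")
def tumor_state(tumor_net):
    return simulate_hemodynamics(tumor_net, FlowConfig())


@pytest.fixture(scope="session")
def tree_net():
    return make_bifurcation_tree(depth=3, root_pressure=40.0, leaf_pressure=15.0)


@pytest.fixture(scope="session")
def tree_state(tree_net):
    return simulate_hemodynamics(tree_net, FlowConfig())
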