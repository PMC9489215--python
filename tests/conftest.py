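import numpy as np
import pytest

import oscreen as oc
from oscreen.screen import fixture_library


@pytest.fixture(scope="session")
def repressilator():
    return oc.parse_topology("A B -1\nB C -1\nC A -1")


@pytest.fixture(scope="session")
def activator_inhibitor():
    return oc.parse_topology("A A +1\nA B +1\nB A -1")


@pytest.fixture(scope="session")
def fixtures():
    """Named (topology, frozen oscillatory ParameterSet) pairs."""
    return fixture_library()


@pytest.fixture(scope="session")
def ai_oscillator(fixtures):
    """Activator-inhibitor fixture with its frozen oscillatory set."""
    return fixtures["activator_inhibitor"]


@pytest.fixture(scope="session")
def repressilator_oscillator(fixtures):
    return fixtures["repressilator"]


@pytest.fixture(scope="session")
def ai_features(ai_oscillator):
    """Deterministic trajectory, features and B-peak state of the
    activator-inhibitor fixture (shared across stochastic tests)."""
    t, p = ai_oscillator
    traj = oc.simulate_deterministic(t, p)
    feats = oc.detect_oscillation(traj)
    assert feats.oscillatory
    return traj, feats, oc.state_at_b_peak(traj)


def unregulated_gene_params(delta=2.0, r=0.2, k_basal=0.01):
    """2-node chain A -> B; node A (index 0) has no regulators, so its
    dynamics reduce to dA/dt = k_basal + delta - r A."""
    t = oc.SignedTopology.from_links(2, [("A", "B", 1)])
    v = np.array([[0.0, 1.0], [0.0, 0.0]])
    K = np.array([[0.0, 5.0], [0.0, 0.0]])
    deltav = np.array([delta, 0.0])
    rv = np.array([r, r])
    return t, oc.ParameterSet(t, v, K, deltav, rv, k_basal=k_basal)
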