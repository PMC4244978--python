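import numpy as np
import pytest

import boltzmet as bm


@pytest.fixture(scope="session")
def abc_equal():
    """Closed A⇄B⇄C chain, equal potentials, N = 6."""
    return bm.make_abc_fixture((0.0, 0.0, 0.0), 6)


@pytest.fixture(scope="session")
def abc_tilted():
    """Closed A⇄B⇄C chain with unequal potentials, N = 6."""
    return bm.make_abc_fixture((0.0, 0.4, -0.3), 6)


@pytest.fixture(scope="session")
def tca_ecoli():
    return bm.make_tca_fixture("ecoli")


@pytest.fixture(scope="session")
def tca_chlorobium():
    return bm.make_tca_fixture("chlorobium")


@pytest.fixture(scope="session")
def tca_cyano():
    return bm.make_tca_fixture("cyano")


def enumerated_distribution(net, n_total):
    """Exact multinomial-Boltzmann distribution over the closed state space."""
    from scipy.special import logsumexp

    states = bm.enumerate_states(net, n_total)
    logw = np.array([bm.log_state_weight(s, net).neg_A_over_kBT for s in states])
    p = np.exp(logw - logsumexp(logw))
    return states, p


def replay_dynamic_states(traj, net, state0):
    """Per-step dynamic count matrix reconstructed from the event stream."""
    dyn_idx = np.flatnonzero(net.dynamic_mask)
    cols = net.stoich[dyn_idx, :]
    deltas = (
        cols[:, traj.reaction_idx].T
        * traj.direction[:, None]
        * traj.accepted[:, None]
    )
    return state0.counts[dyn_idx] + np.cumsum(deltas, axis=0)
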