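"""Mk likelihood, ARD fitting, stochastic maps and CTMC simulation."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import morphorates as mr
from morphorates.discrete_traits import _tip_codes, mk_loglik


def enumeration_loglik(tree, tips, Q, prior):
    """Brute-force likelihood by summing over all interior assignments."""
    k = len(Q)
    n_tips = tree.n_tips
    interior = [i for i in range(tree.n_nodes) if i >= n_tips]
    P = {i: expm(Q * tree.branch_lengths[i]) for i in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(interior)):
        state = dict(zip(interior, assign))
        for i, s in enumerate(tips):
            state[i] = int(s)
        lik = prior[state[tree.root]]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                lik *= P[i][state[p], state[i]]
        total += lik
    return np.log(total)


def test_pruning_matches_enumeration(tree4):
    Q = np.array([[-0.7, 0.4, 0.3],
                  [0.2, -0.5, 0.3],
                  [0.1, 0.6, -0.7]])
    prior = np.array([0.2, 0.3, 0.5])
    for tips in [(0, 1, 2, 0), (2, 2, 2, 2), (0, 0, 1, 2)]:
        tips = np.array(tips)
        got = mk_loglik(tree4, tips, Q, prior)
        want = enumeration_loglik(tree4, tips, Q, prior)
        assert got == pytest.approx(want, abs=1e-8)


def test_fit_mk_ard_recovers_rates(tree64):
    Q = np.array([[-0.08, 0.08], [0.02, -0.02]])
    states = mr.simulate_mk(tree64, Q, seed=1, states=("a", "b"))
    fit = mr.fit_mk_ard(states, tree64, seed=0)
    assert fit.states == ("a", "b")
    assert np.allclose(fit.Q.sum(axis=1), 0.0, atol=1e-10)
    # the fitted likelihood beats the likelihood at a mis-scaled matrix
    tips, _ = _tip_codes(states, tree64, fit.states)
    prior = np.full(2, 0.5)
    assert fit.loglik >= mk_loglik(tree64, tips, Q, prior) - 1e-6
    assert fit.loglik > mk_loglik(tree64, tips, Q * 10, prior)


def test_node_posteriors_sum_to_one(tree64):
    Q = mr.default_q(("x", "y", "z"), rate=0.03)
    states = mr.simulate_mk(tree64, Q, seed=2, states=("x", "y", "z"))
    fit = mr.fit_mk_ard(states, tree64, n_restarts=2, seed=0)
    post = mr.node_state_posteriors(fit)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
    # tip rows are point masses on the observed states
    for i in range(tree64.n_tips):
        assert post[i].max() == pytest.approx(1.0)


def test_simmap_durations_conserve_lengths(tree64):
    Q = mr.default_q(("a", "b"), rate=0.05)
    states = mr.simulate_mk(tree64, Q, seed=3, states=("a", "b"))
    fit = mr.fit_mk_ard(states, tree64, n_restarts=2, seed=0)
    maps = mr.sample_stochastic_maps(fit, n=5, seed=1)
    for sm in maps:
        sm.validate()
        assert sm.total_state_times().sum() == pytest.approx(
            tree64.total_length, rel=1e-12)
        # tip segments end in the observed state
        for i, lab in enumerate(tree64.tip_labels):
            assert sm.states[sm.node_states[i]] == states[lab]


def test_simmap_node_frequencies_match_posteriors(tree16):
    Q = np.array([[-0.3, 0.3], [0.15, -0.15]])
    states = mr.simulate_mk(tree16, Q, seed=5, states=("a", "b"))
    fit = mr.fit_mk_ard(states, tree16, n_restarts=2, seed=0)
    post = mr.node_state_posteriors(fit)
    n = 600
    maps = mr.sample_stochastic_maps(fit, n=n, seed=2)
    counts = np.zeros_like(post)
    for sm in maps:
        counts[np.arange(tree16.n_nodes), sm.node_states] += 1
    freq = counts / n
    se = np.sqrt(np.maximum(post * (1 - post), 1e-12) / n)
    assert np.all(np.abs(freq - post) <= 3 * se + 1e-9)


def test_simulate_history_validates(tree64):
    Q = mr.default_q(("a", "b", "c"), rate=0.04)
    sm = mr.simulate_mk_history(tree64, Q, seed=4)
    sm.validate()
    assert sm.total_state_times().sum() == pytest.approx(
        tree64.total_length, rel=1e-12)


def test_simulate_mk_rejects_bad_q(tree64):
    with pytest.raises(ValueError):
        mr.simulate_mk(tree64, np.array([[0.1, -0.1], [0.2, -0.2]]))


def test_state_covariances_consistency(tree16):
    Q = mr.default_q(("a", "b"), rate=0.1)
    sm = mr.simulate_mk_history(tree16, Q, seed=6)
    Cs = sm.state_covariances()
    # summed over states, the state covariances rebuild the BM covariance
    np.testing.assert_allclose(Cs.sum(axis=0), tree16.vcv(), atol=1e-10)
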