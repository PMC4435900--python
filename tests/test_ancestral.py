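"""Two-state CTMC likelihood, rate fitting, marginals, gain calls."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import motiftrace as mt
from motiftrace.ancestral import (Mk2AncestralModel, RateParams, fit_rates,
                                  infer_gains, marginal_ancestral,
                                  pruning_loglik, transition_matrix)
from motiftrace.simulate import sample_tree, simulate_binary_character


# ---------------------------------------------------------------------------
# transition matrix

def test_zero_time_and_zero_rates_are_identity():
    assert np.allclose(transition_matrix(RateParams(1, 2), 0.0), np.eye(2))
    assert np.allclose(transition_matrix(RateParams(0, 0), 5.0), np.eye(2))


def test_symmetric_rates_closed_form():
    P = transition_matrix(RateParams(1, 1), float(np.log(2)))
    assert P[0, 1] == pytest.approx(0.375)
    assert P[0, 0] == pytest.approx(0.625)


def test_long_time_reaches_stationary_rows():
    a, b = 0.7, 0.2
    P = transition_matrix(RateParams(a, b), 50.0 / (a + b))
    pi = np.array([b / (a + b), a / (a + b)])
    assert np.allclose(P, np.vstack([pi, pi]), atol=1e-12)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        transition_matrix(RateParams(1, 1), -0.1)


@settings(max_examples=60, deadline=None)
@given(st.floats(0.01, 5.0), st.floats(0.01, 5.0),
       st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_rows_sum_to_one_and_chapman_kolmogorov(a, b, t1, t2):
    r = RateParams(a, b)
    P1, P2 = transition_matrix(r, t1), transition_matrix(r, t2)
    assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(P1 @ P2, transition_matrix(r, t1 + t2), atol=1e-10)


# ---------------------------------------------------------------------------
# pruning likelihood

def brute_force_loglik(tree, states, rates, prior="stationary"):
    """Exhaustive sum over all internal-state assignments."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    leafmap = {tree.labels[v]: v for v in tree.leaf_indices}
    P = {v: transition_matrix(rates, float(tree.lengths[v]))
         for v in range(tree.n_nodes)}
    pi = np.array([0.5, 0.5]) if prior == "flat" else rates.stationary()
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st_map = dict(zip(internal, assign))
        for lab, s in states.items():
            st_map[leafmap[lab]] = s
        p = pi[st_map[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st_map[tree.parent[v]], st_map[v]]
        total += p
    with np.errstate(divide="ignore"):
        return float(np.log(total))


def test_two_leaf_closed_form(two_leaf_tree):
    ll = pruning_loglik(two_leaf_tree, {"a": 1, "b": 1}, RateParams(1, 1),
                        root_prior="flat")
    # 0.5 * (P01^2 + P11^2) = 0.5 (0.375^2 + 0.625^2) = 0.265625
    assert np.exp(ll) == pytest.approx(0.265625, abs=1e-12)


def test_impossible_configuration_is_minus_inf(two_leaf_tree):
    ll = pruning_loglik(two_leaf_tree, {"a": 1, "b": 0}, RateParams(0, 0),
                        root_prior="flat")
    assert ll == -np.inf


def test_missing_leaf_state_reported(two_leaf_tree):
    with pytest.raises(ValueError, match="b"):
        pruning_loglik(two_leaf_tree, {"a": 1}, RateParams(1, 1))


def test_pruning_matches_enumeration(rng):
    for _ in range(25):
        tree = sample_tree(int(rng.integers(3, 7)), 1.0,
                           int(rng.integers(1 << 30)))
        rates = RateParams(float(rng.uniform(0.05, 2)),
                           float(rng.uniform(0.05, 2)))
        states = {lab: int(rng.integers(2)) for lab in tree.leaf_labels}
        for prior in ("flat", "stationary"):
            got = pruning_loglik(tree, states, rates, prior)
            want = brute_force_loglik(tree, states, rates, prior)
            assert got == pytest.approx(want, abs=1e-8)


def test_loglik_invariant_under_child_reordering(five_leaf_tree):
    t = five_leaf_tree
    states = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 1}
    base = pruning_loglik(t, states, RateParams(0.5, 0.8))
    flipped = mt.Phylogeny(t.labels, t.parent, t.lengths)
    for v in range(flipped.n_nodes):
        flipped.children[v] = flipped.children[v][::-1]
    flipped._postorder = flipped._order(post=True)
    flipped._preorder = flipped._order(post=False)
    again = pruning_loglik(flipped, states, RateParams(0.5, 0.8))
    assert again == pytest.approx(base, abs=1e-12)


def test_vectorised_characters_match_scalar(five_leaf_tree):
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, size=(10, 5))
    rates = RateParams(0.4, 0.9)
    ll = pruning_loglik(five_leaf_tree, X, rates)
    for i in range(10):
        states = dict(zip(five_leaf_tree.leaf_labels, X[i]))
        assert ll[i] == pytest.approx(
            pruning_loglik(five_leaf_tree, states, rates), abs=1e-12)


# ---------------------------------------------------------------------------
# marginals

def clamping_marginal(tree, states, rates, prior, node_label):
    """Oracle: posterior at a node from likelihoods with the node clamped."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    leafmap = {tree.labels[v]: v for v in tree.leaf_indices}
    P = {v: transition_matrix(rates, float(tree.lengths[v]))
         for v in range(tree.n_nodes)}
    pi = np.array([0.5, 0.5]) if prior == "flat" else rates.stationary()
    target = tree.index_of(node_label)
    lik = np.zeros(2)
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st_map = dict(zip(internal, assign))
        for lab, s in states.items():
            st_map[leafmap[lab]] = s
        p = pi[st_map[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st_map[tree.parent[v]], st_map[v]]
        lik[st_map[target]] += p
    return lik / lik.sum()


def test_symmetric_discordant_leaves_give_half_half(two_leaf_tree):
    marg = marginal_ancestral(two_leaf_tree, {"a": 1, "b": 0},
                              RateParams(1, 1), root_prior="flat")
    assert marg["root"] == pytest.approx([0.5, 0.5], abs=1e-12)


def test_marginals_match_clamping_oracle(rng):
    for _ in range(10):
        tree = sample_tree(int(rng.integers(3, 7)), 1.0,
                           int(rng.integers(1 << 30)))
        rates = RateParams(float(rng.uniform(0.1, 2)),
                           float(rng.uniform(0.1, 2)))
        states = {lab: int(rng.integers(2)) for lab in tree.leaf_labels}
        marg = marginal_ancestral(tree, states, rates, "stationary")
        for lab in tree.labels:
            want = clamping_marginal(tree, states, rates, "stationary", lab)
            assert np.abs(marg[lab] - want).max() < 1e-10
        assert all(abs(m.sum() - 1) < 1e-9 for m in marg.values())


def test_leaf_marginals_degenerate_on_observations(five_leaf_tree):
    states = {"A": 1, "B": 0, "C": 1, "D": 1, "E": 0}
    marg = marginal_ancestral(five_leaf_tree, states, RateParams(0.5, 0.5))
    for leaf, s in states.items():
        assert marg[leaf][s] == pytest.approx(1.0, abs=1e-12)


def test_no_loss_model_presence_monotone_from_root():
    """With b = 0 and all leaves present, P(present) cannot decrease from
    parent to child along any root-to-leaf path."""
    tree = sample_tree(8, 1.0, seed=5)
    states = {lab: 1 for lab in tree.leaf_labels}
    marg = marginal_ancestral(tree, states, RateParams(0.5, 0.0),
                              root_prior="flat")
    for v in tree.preorder:
        p = tree.parent[v]
        if p >= 0:
            assert marg[tree.labels[v]][1] >= \
                marg[tree.labels[p]][1] - 1e-12


# ---------------------------------------------------------------------------
# rate fitting

def test_all_absent_hits_gain_boundary(five_leaf_tree):
    states = {lab: 0 for lab in "ABCDE"}
    rates, ll, boundary = fit_rates(five_leaf_tree, states)
    assert boundary
    # MLE pushes toward all root-prior mass on state 0: tiny gain rate,
    # log likelihood approaching log(1) = 0
    assert rates.a <= 1e-3
    assert -0.01 < ll <= 0.0


def test_fitted_loglik_at_least_grid_starts(five_leaf_tree):
    states = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 1}
    rates, ll, _ = fit_rates(five_leaf_tree, states)
    gridpts = np.exp(np.linspace(np.log(1e-4), np.log(20.0), 5))
    for ga in gridpts:
        for gb in gridpts:
            assert ll >= pruning_loglik(five_leaf_tree, states,
                                        RateParams(ga, gb)) - 1e-9


def test_fit_deterministic(five_leaf_tree):
    states = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 1}
    r1 = fit_rates(five_leaf_tree, states)
    r2 = fit_rates(five_leaf_tree, states)
    assert r1 == r2


def test_joint_rate_recovery_improves_with_characters():
    """RMSE of jointly fitted rates shrinks from 20 to 200 characters
    (8 replicates)."""
    tree = sample_tree(32, 1.0, seed=13)
    a, b = 0.5, 0.2
    rng = np.random.default_rng(7)

    def rmse(n_chars, reps=8):
        errs = []
        for _ in range(reps):
            chars = [simulate_binary_character(
                tree, a, b, 0, int(rng.integers(1 << 30)))
                for _ in range(n_chars)]
            X = np.array([[c.leaf_states[lab]
                           for lab in tree.leaf_labels] for c in chars])
            rates, _, _ = fit_rates(tree, X)
            errs.append((rates.a - a) ** 2 + (rates.b - b) ** 2)
        return float(np.sqrt(np.mean(errs)))

    assert rmse(200) < rmse(20)


# ---------------------------------------------------------------------------
# gain inference

def test_all_absent_character_calls_none(five_leaf_tree):
    marg = {lab: np.array([1.0, 0.0]) for lab in five_leaf_tree.labels}
    rep = infer_gains(five_leaf_tree, marg, tau=0.92)
    assert rep.gain_count == 0
    assert rep.call == "none"
    assert rep.scaled_likelihood == 0.0


def test_all_present_character_gains_at_root(five_leaf_tree):
    marg = {lab: np.array([0.02, 0.98]) for lab in five_leaf_tree.labels}
    rep = infer_gains(five_leaf_tree, marg, tau=0.92, root_prior_p1=0.3)
    assert rep.call == "once"
    assert rep.gain_events[0][0] == "r"
    assert rep.scaled_likelihood == pytest.approx(0.98)


def test_clade_confined_presence_gains_at_stem():
    """Presence confined to the (C, D) clade with a long stem branch
    yields a single gain at the clade's stem node w."""
    labels = ["r", "u", "A", "B", "v", "w", "C", "D", "E"]
    parent = [-1, 0, 1, 1, 0, 4, 5, 5, 4]
    lengths = [0.0, 0.4, 0.6, 0.7, 0.3, 1.5, 0.2, 0.3, 1.1]
    tree = mt.Phylogeny(labels, parent, lengths)
    states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0}
    model = Mk2AncestralModel(tau=0.92).fit(tree, states)
    rep = model.report_
    assert rep.call == "once"
    assert rep.gain_count == 1
    assert rep.gain_events[0][0] == "w"
    assert rep.scaled_likelihood >= 0.92


def test_two_separate_clades_call_multiple(five_leaf_tree):
    marg = {lab: np.array([1.0, 0.0]) for lab in five_leaf_tree.labels}
    for lab in ("A", "w", "C", "D"):
        marg[lab] = np.array([0.01, 0.99])
    rep = infer_gains(five_leaf_tree, marg, tau=0.92)
    assert rep.call == "multiple"
    assert rep.gain_count == 2


def test_tau_validation(five_leaf_tree):
    marg = {lab: np.array([1.0, 0.0]) for lab in five_leaf_tree.labels}
    for bad in (0.5, 1.0, 0.2):
        with pytest.raises(ValueError):
            infer_gains(five_leaf_tree, marg, tau=bad)


def test_estimator_interface(five_leaf_tree):
    states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0}
    model = Mk2AncestralModel(root_prior="flat", tau=0.9)
    assert model.get_params()["tau"] == 0.9
    model.fit(five_leaf_tree, states, motif="m1")
    assert model.report_.motif == "m1"
    hard = model.predict()
    assert hard["C"] == 1 and hard["A"] == 0
    assert set(model.predict_marginals()) == set(five_leaf_tree.labels)
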