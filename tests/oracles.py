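"""Independent oracle implementations shared by the test suite.

These deliberately avoid the package's own algorithms: likelihoods are
exhaustive sums over internal-state assignments, orthology classes come
from a direct transcription of the best-hit rules, and repeats come from a
cubic scanner.
"""

import itertools

import numpy as np

from motiftrace.ancestral import transition_matrix


def enumeration_loglik(tree, states, rates, prior="stationary"):
    """Likelihood by exhaustive enumeration of internal states."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    leafmap = {tree.labels[v]: v for v in tree.leaf_indices}
    P = {v: transition_matrix(rates, float(tree.lengths[v]))
         for v in range(tree.n_nodes)}
    pi = np.array([0.5, 0.5]) if prior == "flat" else rates.stationary()
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for lab, s in states.items():
            st[leafmap[lab]] = s
        p = pi[st[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    with np.errstate(divide="ignore"):
        return float(np.log(total))


def clamped_marginals(tree, states, rates, prior="stationary"):
    """Posterior state marginals at every node by clamping/enumeration."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    leafmap = {tree.labels[v]: v for v in tree.leaf_indices}
    P = {v: transition_matrix(rates, float(tree.lengths[v]))
         for v in range(tree.n_nodes)}
    pi = np.array([0.5, 0.5]) if prior == "flat" else rates.stationary()
    lik = {lab: np.zeros(2) for lab in tree.labels}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for lab, s in states.items():
            st[leafmap[lab]] = s
        p = pi[st[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st[tree.parent[v]], st[v]]
        for v in range(tree.n_nodes):
            lik[tree.labels[v]][st[v]] += p
    return {lab: v / v.sum() for lab, v in lik.items()}


def brute_force_pair_classes(cross, withinA, withinB):
    """Direct transcription of the best-hit / ortholog / one-to-one rules.

    cross: dict (a, b) -> score over all A x B pairs; withinA/withinB:
    dict (p, q) -> score between distinct proteins of one genome.
    Returns dict (a, b) -> class for every pair that receives one.
    """
    a_ids = sorted({a for a, _ in cross})
    b_ids = sorted({b for _, b in cross})

    def best(query, candidates, get):
        scored = [(get(c), c) for c in candidates]
        top = max(s for s, _ in scored)
        return min(c for s, c in scored if s == top)  # lexicographic tie

    best_in_B = {a: best(a, b_ids, lambda b: cross[(a, b)]) for a in a_ids}
    best_in_A = {b: best(b, a_ids, lambda a: cross[(a, b)]) for b in b_ids}
    out = {}
    for a in a_ids:
        b = best_in_B[a]
        if best_in_A[b] == a:
            s = cross[(a, b)]
            paraA = max([v for (p, _), v in withinA.items() if p == a],
                        default=-np.inf)
            paraB = max([v for (p, _), v in withinB.items() if p == b],
                        default=-np.inf)
            out[(a, b)] = ("one_to_one"
                           if paraA <= s and paraB <= s else "ortholog")
        else:
            out[(a, b)] = "best_hit"
    for b in b_ids:
        a = best_in_A[b]
        if (a, b) not in out:
            out[(a, b)] = "best_hit"
    return out
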