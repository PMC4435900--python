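"""Two-state ancestral character estimation on a species tree.

The presence/absence of a motif evolves as a continuous-time Markov chain
on {0 = absent, 1 = present} with unequal gain rate ``a`` (0→1) and loss
rate ``b`` (1→0) per unit branch length.  The likelihood of observed leaf
states is computed by Felsenstein's pruning algorithm with per-node
scaling; rates are fitted by maximum likelihood in log-rate space from a
grid of starts; marginal posterior state probabilities at every node come
from a combined post-order/pre-order sweep; and gain/loss events are called
by thresholding the marginals, yielding the single-vs-multiple acquisition
call per motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .tree import Phylogeny

__all__ = [
    "RateParams", "GainReport", "Mk2AncestralModel", "transition_matrix",
    "pruning_loglik", "fit_rates", "marginal_ancestral", "infer_gains",
]

RootPrior = Literal["stationary", "flat"]
LOG_RATE_BOUNDS = (np.log(1e-8), np.log(1e3))


@dataclass(frozen=True)
class RateParams:
    a: float  # gain rate 0 -> 1
    b: float  # loss rate 1 -> 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("rates must be >= 0")

    def stationary(self) -> np.ndarray:
        s = self.a + self.b
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.b / s, self.a / s])


def transition_matrix(rates: RateParams, t: float) -> np.ndarray:
    """P(t) for the two-state chain: closed form.

    P01(t) = a/(a+b) * (1 - exp(-(a+b) t)) and symmetrically; a = b = 0 (or
    t = 0) gives the identity.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    a, b = rates.a, rates.b
    s = a + b
    if s == 0 or t == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array([[(b + a * e) / s, (a * (1 - e)) / s],
                     [(b * (1 - e)) / s, (a + b * e) / s]])


# ---------------------------------------------------------------------------
# pruning

def _leaf_state_array(tree: Phylogeny,
                      leaf_states: Mapping[str, int] | np.ndarray
                      ) -> np.ndarray:
    """(n_chars, n_leaves) integer array in tree leaf order."""
    if isinstance(leaf_states, Mapping):
        missing = [lab for lab in tree.leaf_labels if lab not in leaf_states]
        if missing:
            raise ValueError(f"missing leaf states for {missing}")
        arr = np.array([[int(leaf_states[lab]) for lab in tree.leaf_labels]])
    else:
        arr = np.atleast_2d(np.asarray(leaf_states, dtype=int))
        if arr.shape[1] != tree.n_leaves:
            raise ValueError("leaf state array width must equal the number "
                             "of leaves (tree leaf order)")
    if np.any((arr != 0) & (arr != 1)):
        raise ValueError("leaf states must be 0 or 1")
    return arr


def _edge_matrices(tree: Phylogeny, rates: RateParams) -> np.ndarray:
    P = np.empty((tree.n_nodes, 2, 2))
    for v in range(tree.n_nodes):
        P[v] = (transition_matrix(rates, float(tree.lengths[v]))
                if tree.parent[v] >= 0 else np.eye(2))
    return P


def _root_prior_vector(rates: RateParams, root_prior: RootPrior
                       ) -> np.ndarray:
    if root_prior == "flat":
        return np.array([0.5, 0.5])
    if root_prior == "stationary":
        return rates.stationary()
    raise ValueError(f"unknown root prior {root_prior!r}")


def _pruning_pass(tree: Phylogeny, states: np.ndarray, P: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Post-order partial likelihoods with per-node scaling.

    Returns (down, logscale): down[v] has shape (n_chars, 2) with
    down[v][c, i] proportional to P(leaf data below v | state at v = i);
    logscale[c] accumulates the log of the scaling factors.
    """
    n_chars = states.shape[0]
    down = np.ones((tree.n_nodes, n_chars, 2))
    logscale = np.zeros(n_chars)
    leaf_col = {v: j for j, v in enumerate(tree.leaf_indices)}
    for v in tree.postorder:
        if tree.is_leaf[v]:
            s = states[:, leaf_col[v]]
            down[v] = 0.0
            down[v][np.arange(n_chars), s] = 1.0
        else:
            acc = np.ones((n_chars, 2))
            for c in tree.children[v]:
                acc *= down[c] @ P[c].T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            down[v] = acc / mx[:, None]
    return down, logscale


def pruning_loglik(tree: Phylogeny,
                   leaf_states: Mapping[str, int] | np.ndarray,
                   rates: RateParams,
                   root_prior: RootPrior = "stationary") -> float | np.ndarray:
    """Log likelihood of the leaf states under the two-state chain.

    ``leaf_states`` is a mapping leaf label -> {0, 1} for one character, or
    an (n_chars, n_leaves) array (tree leaf order) for many; the return is
    a scalar or an array correspondingly.  Impossible configurations (e.g.
    a = b = 0 with mixed states) return -inf.
    """
    states = _leaf_state_array(tree, leaf_states)
    P = _edge_matrices(tree, rates)
    down, logscale = _pruning_pass(tree, states, P)
    pi = _root_prior_vector(rates, root_prior)
    lik = down[tree.root] @ pi
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale
    return float(ll[0]) if isinstance(leaf_states, Mapping) else ll


# ---------------------------------------------------------------------------
# rate fitting

def fit_rates(tree: Phylogeny, leaf_states: Mapping[str, int] | np.ndarray,
              root_prior: RootPrior = "stationary",
              grid: int = 5) -> tuple[RateParams, float, bool]:
    """Maximum-likelihood gain/loss rates.

    Optimises the summed log likelihood over (log a, log b) with L-BFGS-B
    from the best of a ``grid`` x ``grid`` log-spaced start grid.  With an
    array of characters the rates are shared (summed log likelihood).

    Returns (rates, logL, boundary_flag); the flag is set when all leaves
    share one state, in which case the MLE pushes the rate toward the
    absent state to its lower bound.
    """
    states = _leaf_state_array(tree, leaf_states)
    boundary = bool(np.all(states == states[0, 0]))

    def negll(logab: np.ndarray) -> float:
        r = RateParams(float(np.exp(logab[0])), float(np.exp(logab[1])))
        ll = pruning_loglik(tree, states, r, root_prior)
        total = float(np.sum(ll))
        return 1e12 if not np.isfinite(total) else -total

    lo, hi = np.log(1e-4), np.log(20.0)
    gridpts = np.linspace(lo, hi, grid)
    starts = [(ga, gb) for ga in gridpts for gb in gridpts]
    best_start = min(starts, key=lambda s: negll(np.array(s)))
    res = minimize(negll, np.array(best_start), method="L-BFGS-B",
                   bounds=[LOG_RATE_BOUNDS] * 2)
    cand = [(res.fun, res.x)] if np.isfinite(res.fun) else []
    cand.append((negll(np.array(best_start)), np.array(best_start)))
    fun, x = min(cand, key=lambda c: c[0])
    rates = RateParams(float(np.exp(x[0])), float(np.exp(x[1])))
    return rates, -float(fun), boundary


# ---------------------------------------------------------------------------
# marginal reconstruction

def marginal_ancestral(tree: Phylogeny,
                       leaf_states: Mapping[str, int] | np.ndarray,
                       rates: RateParams,
                       root_prior: RootPrior = "stationary"
                       ) -> dict[str, np.ndarray]:
    """Exact marginal posterior P(state | all leaf data) at every node.

    Combines the post-order (pruning) pass with a pre-order (outside) pass;
    leaf marginals are degenerate on the observed states.  Returns a dict
    node label -> array of shape (2,) (or (n_chars, 2) for array input).
    """
    states = _leaf_state_array(tree, leaf_states)
    n_chars = states.shape[0]
    P = _edge_matrices(tree, rates)
    down, _ = _pruning_pass(tree, states, P)
    pi = _root_prior_vector(rates, root_prior)

    up = np.empty((tree.n_nodes, n_chars, 2))
    up[tree.root] = pi[None, :]
    for v in tree.preorder:
        for c in tree.children[v]:
            sib = np.ones((n_chars, 2))
            for s in tree.children[v]:
                if s != c:
                    sib *= down[s] @ P[s].T
            msg = up[v] * sib            # (n_chars, 2) at parent states
            up[c] = msg @ P[c]
            mx = up[c].max(axis=1)
            mx[mx == 0] = 1.0
            up[c] /= mx[:, None]

    out: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        post = up[v] * down[v]
        tot = post.sum(axis=1)
        if np.any(tot == 0):
            raise ValueError("zero-likelihood configuration: marginals "
                             "undefined (e.g. a = b = 0 with mixed states)")
        post = post / tot[:, None]
        out[tree.labels[v]] = (post[0] if isinstance(leaf_states, Mapping)
                               else post)
    return out


# ---------------------------------------------------------------------------
# gain inference

@dataclass
class GainReport:
    """Per-motif gain/loss summary from thresholded node marginals."""

    motif: str
    rates: RateParams
    loglik: float
    #: (node, parent or "" for the root, P1 at node, P1 at parent or prior)
    gain_events: list[tuple[str, str, float, float]]
    loss_events: list[tuple[str, str, float, float]]
    call: Literal["once", "multiple", "uncertain", "none"]
    scaled_likelihood: float
    boundary_fit: bool = False

    @property
    def gain_count(self) -> int:
        return len(self.gain_events)


def infer_gains(tree: Phylogeny, marginals: Mapping[str, np.ndarray],
                tau: float = 0.92, root_prior_p1: float = 0.5,
                motif: str = "", rates: RateParams | None = None,
                loglik: float = float("nan"),
                boundary_fit: bool = False) -> GainReport:
    """Call gain and loss events from node marginals.

    Each node is hard-called present (P1 >= tau), absent (P1 <= 1 - tau) or
    uncertain.  A gain is a confidently present node whose parent is *not*
    present (P1 < tau) — the transition falls somewhere on or above the
    gain branch, and the gain node is its first confident carrier; a
    present root counts as a gain (acquisition at or before the root).  A
    loss is a confidently absent node with a confidently present parent.
    The acquisition call is "once" for exactly one gain, "multiple" for two
    or more, "none" when no node is confidently present, and "uncertain"
    when presence exists only in the uncertain zone.  The scaled likelihood
    of gain is the largest P1 over the gain nodes.
    """
    if not 0.5 < tau < 1:
        raise ValueError("tau must be in (0.5, 1)")

    def p1(label: str) -> float:
        m = np.asarray(marginals[label], dtype=float).ravel()
        return float(m[1])

    def callof(p: float) -> int:  # 1 present, 0 absent, -1 uncertain
        if p >= tau:
            return 1
        if p <= 1 - tau:
            return 0
        return -1

    calls = {lab: callof(p1(lab)) for lab in tree.labels}
    gains: list[tuple[str, str, float, float]] = []
    losses: list[tuple[str, str, float, float]] = []
    for v in tree.preorder:
        lab = tree.labels[v]
        p = tree.parent[v]
        if p < 0:
            # a present root means the motif was acquired at or before the
            # root: count it as the character's (single) gain event
            if calls[lab] == 1:
                gains.append((lab, "", p1(lab), root_prior_p1))
            continue
        plab = tree.labels[p]
        if calls[lab] == 1 and calls[plab] != 1:
            gains.append((lab, plab, p1(lab), p1(plab)))
        elif calls[lab] == 0 and calls[plab] == 1:
            losses.append((lab, plab, p1(lab), p1(plab)))

    any_present = any(c == 1 for c in calls.values())
    if len(gains) >= 2:
        call = "multiple"
    elif len(gains) == 1:
        call = "once"
    elif not any_present and all(c == 0 for c in calls.values()):
        call = "none"
    elif not any_present:
        call = "none" if not any(c == -1 for c in calls.values()) \
            else "uncertain"
    else:  # pragma: no cover - present nodes always induce a topmost gain
        call = "uncertain"
    scaled = max((g[2] for g in gains), default=0.0)
    return GainReport(motif=motif,
                      rates=rates if rates is not None else RateParams(0, 0),
                      loglik=loglik, gain_events=gains, loss_events=losses,
                      call=call, scaled_likelihood=scaled,
                      boundary_fit=boundary_fit)


# ---------------------------------------------------------------------------
# estimator facade

class Mk2AncestralModel(BaseEstimator):
    """Two-state ancestral reconstruction as an sklearn-style estimator.

    Parameters
    ----------
    root_prior : {"stationary", "flat"}, default "stationary"
        Root state distribution: the chain's stationary distribution
        (b/(a+b), a/(a+b)) or a flat 50/50 prior.
    tau : float, default 0.92
        Confidence threshold for hard presence/absence calls.
    grid : int, default 5
        Side of the log-spaced start grid for rate fitting.

    Attributes (after ``fit``)
    ----------
    rates_ : RateParams — fitted gain/loss rates.
    loglik_ : float — maximised log likelihood.
    boundary_ : bool — all leaves shared one state (boundary MLE).
    marginals_ : dict node label -> (2,) posterior state probabilities.
    report_ : GainReport — thresholded gain/loss events and the call.
    """

    def __init__(self, root_prior: RootPrior = "stationary",
                 tau: float = 0.92, grid: int = 5):
        self.root_prior = root_prior
        self.tau = tau
        self.grid = grid

    def fit(self, tree: Phylogeny, leaf_states: Mapping[str, int],
            motif: str = "") -> "Mk2AncestralModel":
        rates, ll, boundary = fit_rates(tree, leaf_states, self.root_prior,
                                        self.grid)
        self.tree_ = tree
        self.rates_ = rates
        self.loglik_ = ll
        self.boundary_ = boundary
        self.marginals_ = marginal_ancestral(tree, leaf_states, rates,
                                             self.root_prior)
        prior_p1 = float(_root_prior_vector(rates, self.root_prior)[1])
        self.report_ = infer_gains(tree, self.marginals_, self.tau,
                                   root_prior_p1=prior_p1, motif=motif,
                                   rates=rates, loglik=ll,
                                   boundary_fit=boundary)
        return self

    def predict_marginals(self) -> dict[str, np.ndarray]:
        return self.marginals_

    def predict(self) -> dict[str, int]:
        """Hard most-probable state per node."""
        return {lab: int(np.argmax(m)) for lab, m in self.marginals_.items()}
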