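"""Shared fixtures: small trees and deterministic random state."""

import numpy as np
import pytest

from motiftrace.tree import Phylogeny


@pytest.fixture
def two_leaf_tree():
    """Root with two leaves, both branches ln 2."""
    t = float(np.log(2))
    return Phylogeny(["root", "a", "b"], [-1, 0, 0], [0.0, t, t])


@pytest.fixture
def five_leaf_tree():
    """Hand-built asymmetric 5-leaf tree with named internal nodes."""
    #        r
    #      /   \
    #     u     v
    #    / \   / \
    #   A   B w   E
    #            / \  (w has C, D)
    labels = ["r", "u", "A", "B", "v", "w", "C", "D", "E"]
    parent = [-1, 0, 1, 1, 0, 4, 5, 5, 4]
    lengths = [0.0, 0.4, 0.6, 0.7, 0.3, 0.5, 0.2, 0.9, 1.1]
    return Phylogeny(labels, parent, lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
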