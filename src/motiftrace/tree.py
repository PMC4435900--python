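"""Rooted, bifurcating species trees with named internal nodes.

The tree is the backbone of every downstream computation: binary characters
evolve along its branches, and ancestral states are reconstructed on its
nodes.  Internally a :class:`Phylogeny` is a flat array representation
(parent pointers, child lists, branch lengths, labels) optimised for the
post-order/pre-order sweeps used by the pruning algorithm; Newick round-trips
go through dendropy so that quoting, whitespace and label edge cases are
handled by a maintained parser.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted strictly-bifurcating tree with branch lengths.

    Parameters
    ----------
    labels : sequence of str
        One label per node; leaf labels are species names and must be unique.
    parent : sequence of int
        Parent index per node, ``-1`` for the root (exactly one).
    lengths : sequence of float
        Branch length of the edge above each node (ignored for the root).
        All lengths must be >= 0.
    """

    def __init__(self, labels: Sequence[str], parent: Sequence[int],
                 lengths: Sequence[float]):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        n = len(self.labels)
        if not (len(self.parent) == len(self.lengths) == n):
            raise ValueError("labels, parent and lengths must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise ValueError(
                    f"node {self.labels[i]!r} has {len(ch)} children; "
                    "tree must be strictly bifurcating (polytomies rejected)")
        if np.any(self.lengths[np.arange(n) != self.root] < 0):
            raise ValueError("branch lengths must be >= 0")
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        leaves = [self.labels[i] for i in np.flatnonzero(self.is_leaf)]
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf labels must be unique")
        self._postorder = self._order(post=True)
        self._preorder = self._order(post=False)

    # ------------------------------------------------------------------
    def _order(self, post: bool) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        pre = np.array(order, dtype=int)
        return pre[::-1].copy() if post else pre

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        """Node indices, parents always before children."""
        return self._preorder

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no node labelled {label!r}") from None

    def leaves_under(self, node: int | str) -> list[str]:
        """Leaf labels of the clade subtended by ``node``."""
        if isinstance(node, str):
            node = self.index_of(node)
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_leaf[v]:
                out.append(self.labels[v])
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def depth(self, node: int) -> int:
        """Number of edges between ``node`` and the root."""
        d = 0
        while self.parent[node] >= 0:
            node = int(self.parent[node])
            d += 1
        return d

    def path_to_root(self, node: int) -> list[int]:
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        acc = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                acc[v] = acc[p] + self.lengths[v]
        return float(acc[self.is_leaf].max())

    # ------------------------------------------------------------------
    # Newick round-trip
    def to_newick(self) -> str:
        """Newick string with internal node labels and branch lengths."""

        def rec(v: int) -> str:
            if self.is_leaf[v]:
                core = self.labels[v]
            else:
                inner = ",".join(rec(c) for c in self.children[v])
                core = f"({inner}){self.labels[v]}"
            if self.parent[v] >= 0:
                core += f":{self.lengths[v]:.10g}"
            return core

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a rooted Newick string (internal labels required)."""
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=False)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Phylogeny":
        nodes = list(dt.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        labels, parent, lengths = [], [], []
        for nd in nodes:
            lab = None
            if nd.taxon is not None:
                lab = nd.taxon.label
            elif nd.label is not None:
                lab = nd.label
            if lab is None:
                raise ValueError("every node must be labelled "
                                 "(internal labels required)")
            labels.append(lab)
            parent.append(idx[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(nd.edge.length if nd.edge.length is not None else 0.0)
        return cls(labels, parent, lengths)

    # ------------------------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover
        return (f"Phylogeny(n_leaves={self.n_leaves}, "
                f"n_nodes={self.n_nodes}, root={self.labels[self.root]!r})")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return (self.labels == other.labels
                and np.array_equal(self.parent, other.parent)
                and np.allclose(self.lengths, other.lengths))
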