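"""Synthetic evolution of a protein family with mobile disordered-region motifs.

This module generates the study conditions the rest of the package analyses:
a pure-birth (Yule) species tree; binary presence/absence characters evolved
on that tree under a two-state continuous-time Markov chain with unequal
gain (``a``, 0→1) and loss (``b``, 1→0) rates; and per-species proteomes in
which one focal family carries a conserved N-terminal core followed by an
intrinsically disordered C-terminal region with biased composition
(RNQ-rich then AEPV-rich blocks), tandem-repeat tracks, and — for species
whose character state is 1 — one planted instance of each motif.

Everything is driven by a single integer seed and emits a
:class:`TruthBundle` recording the simulated ground truth (node states,
transition events, ortholog map, feature coordinates) so downstream
inferences can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import (ALPHABET, AEPV_PROFILE, GLOBULAR_PROFILE, N_AA,
                       RNQ_PROFILE, ints_to_seq, seq_to_ints)
from .tree import Phylogeny

__all__ = [
    "MotifSpec", "EvolParams", "SimulatedCharacter", "TruthBundle",
    "sample_tree", "simulate_binary_character", "generate_proteome",
    "clade_gain_scenario", "write_dataset",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class MotifSpec:
    """A motif to plant in the disordered region.

    ``consensus`` defines the PWM column-wise: each column puts
    ``1 - noise`` on the consensus letter and spreads ``noise`` uniformly
    over the 19 others.  ``anchor`` is the motif midpoint as a fraction of
    the disordered-region length.
    """

    name: str
    consensus: str
    anchor: float = 0.5
    noise: float = 0.05

    def __post_init__(self) -> None:
        w = len(self.consensus)
        if not 10 <= w <= 25:
            raise ValueError(f"motif width must be in [10, 25], got {w}")
        if not 0.0 <= self.anchor <= 1.0:
            raise ValueError("anchor must lie in [0, 1] (fraction of the "
                             "disordered region)")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")
        bad = set(self.consensus) - set(ALPHABET)
        if bad:
            raise ValueError(f"consensus contains non-canonical letters {bad}")

    @property
    def width(self) -> int:
        return len(self.consensus)

    def pwm(self) -> np.ndarray:
        """(width, 20) column-stochastic emission matrix."""
        w = self.width
        m = np.full((w, N_AA), self.noise / (N_AA - 1))
        for j, c in enumerate(self.consensus):
            m[j, ALPHABET.index(c)] = 1.0 - self.noise
        return m

    def sample(self, rng: np.random.Generator) -> str:
        pwm = self.pwm()
        return "".join(ALPHABET[rng.choice(N_AA, p=pwm[j])]
                       for j in range(self.width))


@dataclass
class EvolParams:
    """Generator settings; defaults are the package's reference conditions."""

    n_taxa: int = 16
    birth_rate: float = 1.0
    gain_rate: float = 0.3          # 0 -> 1 per unit branch length
    loss_rate: float = 0.1          # 1 -> 0 per unit branch length
    root_state: int = 0
    core_length: int = 529
    id_length_mean: float = 530.0
    id_length_sd: float = 80.0
    composition_profiles: Sequence[np.ndarray] = field(
        default_factory=lambda: [RNQ_PROFILE.copy(), AEPV_PROFILE.copy()])
    repeat_tracks: Sequence[tuple[str, int]] = field(
        default_factory=lambda: [("REE", 4), ("AEVP", 4)])
    motif_specs: Sequence[MotifSpec] = field(default_factory=list)
    substitution_rate: float = 0.05     # core/decoys, per residue per unit
    id_substitution_rate: float = 1.0   # disordered background (fast)
    indel_rate: float = 0.0             # per ID residue per unit branch length
    n_decoys: int = 3
    decoy_length: int = 300
    n_paralogs: int = 0
    paralog_divergence: float = 0.8  # extra branch length applied to paralogs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for r in (self.birth_rate, self.gain_rate, self.loss_rate,
                  self.substitution_rate, self.id_substitution_rate,
                  self.indel_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.root_state not in (0, 1):
            raise ValueError("root_state must be 0 or 1")
        for p in self.composition_profiles:
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError("composition profiles must sum to 1")


@dataclass
class SimulatedCharacter:
    """One binary character evolved on the tree."""

    leaf_states: dict[str, int]
    node_states: dict[str, int]
    #: (child-node label, time offset from the branch's parent end, new state)
    events: list[tuple[str, float, int]]


# ---------------------------------------------------------------------------
# tree sampling

def sample_tree(n_taxa: int, birth_rate: float, seed: int) -> Phylogeny:
    """Sample a pure-birth (Yule) species tree with ``n_taxa`` leaves.

    While ``k`` lineages exist the waiting time to the next split is
    Exponential(k * birth_rate); after the last split a final waiting period
    at ``n_taxa`` lineages is appended, so the tree is ultrametric.  Leaves
    are labelled ``sp001, sp002, ...`` and internal nodes ``n001, n002, ...``
    in preorder.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # children[i]: node indices; length[i]: branch above node i
    children: list[list[int]] = [[]]
    length: list[float] = [0.0]
    active = [0]
    # split the root immediately so the process starts with 2 lineages
    for _ in range(2):
        children.append([])
        length.append(0.0)
        children[0].append(len(children) - 1)
    active = list(children[0])

    while True:
        k = len(active)
        t = rng.exponential(1.0 / (k * birth_rate))
        for v in active:
            length[v] += t
        if k == n_taxa:
            break
        pos = int(rng.integers(k))
        v = active[pos]
        kids = []
        for _ in range(2):
            children.append([])
            length.append(0.0)
            children[v].append(len(children) - 1)
            kids.append(len(children) - 1)
        active[pos:pos + 1] = kids

    # flatten to preorder with labels
    labels = [""] * len(children)
    parent = [-1] * len(children)
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    n_int = n_leaf = 0
    for v in order:
        if children[v]:
            n_int += 1
            labels[v] = f"n{n_int:03d}"
        else:
            n_leaf += 1
            labels[v] = f"sp{n_leaf:03d}"
    pos_of = {v: i for i, v in enumerate(order)}
    for v in order:
        for c in children[v]:
            parent[c] = v
    return Phylogeny([labels[v] for v in order],
                     [pos_of[parent[v]] if parent[v] >= 0 else -1
                      for v in order],
                     [length[v] for v in order])


# ---------------------------------------------------------------------------
# binary character evolution

def simulate_binary_character(tree: Phylogeny, a: float, b: float,
                              root_state: int, seed: int) -> SimulatedCharacter:
    """Exact Gillespie simulation of a two-state chain along every branch.

    In state 0 the waiting time to a gain is Exponential(``a``); in state 1
    the waiting time to a loss is Exponential(``b``).  Every flip is recorded
    as (child-node label, offset along the branch, new state).
    """
    if a < 0 or b < 0:
        raise ValueError("rates must be >= 0")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    rng = np.random.default_rng(seed)
    state = np.empty(tree.n_nodes, dtype=int)
    state[tree.root] = root_state
    events: list[tuple[str, float, int]] = []
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        s = int(state[p])
        t, tmax = 0.0, float(tree.lengths[v])
        while True:
            rate = a if s == 0 else b
            if rate == 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= tmax:
                break
            s = 1 - s
            events.append((tree.labels[v], t, s))
        state[v] = s
    node_states = {tree.labels[v]: int(state[v]) for v in range(tree.n_nodes)}
    leaf_states = {lab: node_states[lab] for lab in tree.leaf_labels}
    return SimulatedCharacter(leaf_states, node_states, events)


# ---------------------------------------------------------------------------
# proteome generation

@dataclass
class TruthBundle:
    """Ground truth emitted alongside the simulated proteomes."""

    newick: str
    manifest: dict[str, str]                    # genome id -> species name
    family_of: dict[tuple[str, str], str]       # (genome, protein) -> family
    characters: dict[str, SimulatedCharacter]   # motif name -> character
    motif_coords: dict[tuple[str, str, str], tuple[int, int]]  # 1-based incl.
    cb_segments: dict[tuple[str, str], list[tuple[str, int, int]]]
    repeat_coords: dict[tuple[str, str], list[tuple[str, int, int]]]
    core_end: dict[tuple[str, str], int]        # last core residue, 1-based
    motif_specs: list[MotifSpec] = field(default_factory=list)

    def ortholog_pairs(self) -> set[frozenset]:
        """All cross-genome pairs of proteins in the same family."""
        byfam: dict[str, list[tuple[str, str]]] = {}
        for key, fam in self.family_of.items():
            byfam.setdefault(fam, []).append(key)
        pairs: set[frozenset] = set()
        for members in byfam.values():
            for i, x in enumerate(members):
                for y in members[i + 1:]:
                    if x[0] != y[0]:
                        pairs.add(frozenset((x, y)))
        return pairs

    def presence_matrix(self) -> dict[str, dict[str, int]]:
        """motif -> species -> true leaf state."""
        return {m: dict(c.leaf_states) for m, c in self.characters.items()}

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def key3(k):
            return "|".join(k)
        payload = {
            "newick": self.newick,
            "manifest": self.manifest,
            "family_of": {key3(k): v for k, v in self.family_of.items()},
            "characters": {
                m: {"leaf_states": c.leaf_states,
                    "node_states": c.node_states,
                    "events": [[n, t, s] for n, t, s in c.events]}
                for m, c in self.characters.items()},
            "motif_coords": {key3(k): list(v)
                             for k, v in self.motif_coords.items()},
            "cb_segments": {key3(k): [list(x) for x in v]
                            for k, v in self.cb_segments.items()},
            "repeat_coords": {key3(k): [list(x) for x in v]
                              for k, v in self.repeat_coords.items()},
            "core_end": {key3(k): v for k, v in self.core_end.items()},
            "motif_specs": [dataclasses.asdict(s) for s in self.motif_specs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        d = json.loads(text)

        def unkey(k):
            return tuple(k.split("|"))
        return cls(
            newick=d["newick"],
            manifest=d["manifest"],
            family_of={unkey(k): v for k, v in d["family_of"].items()},
            characters={
                m: SimulatedCharacter(
                    {k: int(v) for k, v in c["leaf_states"].items()},
                    {k: int(v) for k, v in c["node_states"].items()},
                    [(n, float(t), int(s)) for n, t, s in c["events"]])
                for m, c in d["characters"].items()},
            motif_coords={unkey(k): tuple(v)
                          for k, v in d["motif_coords"].items()},
            cb_segments={unkey(k): [tuple(x) for x in v]
                         for k, v in d["cb_segments"].items()},
            repeat_coords={unkey(k): [tuple(x) for x in v]
                           for k, v in d["repeat_coords"].items()},
            core_end={unkey(k): int(v) for k, v in d["core_end"].items()},
            motif_specs=[MotifSpec(**s) for s in d.get("motif_specs", [])],
        )


def _draw_seq(rng: np.random.Generator, profile: np.ndarray,
              length: int) -> np.ndarray:
    return rng.choice(N_AA, size=length, p=profile)


class _NodeSeq:
    """Evolving focal protein plus the truth coordinates riding on it.

    ``cb`` and ``rep`` hold (label, start, end) with 0-based start and
    exclusive end; ``anchors`` holds motif-name -> 0-based insertion start.
    Single-residue indels (restricted to the disordered region) shift or
    resize these coordinates so they stay consistent with the sequence.
    """

    __slots__ = ("seq", "profile", "rates", "cb", "rep", "anchors")

    def __init__(self, seq, profile, rates, cb, rep, anchors):
        self.seq = seq
        self.profile = profile
        self.rates = rates
        self.cb = cb
        self.rep = rep
        self.anchors = anchors

    def copy(self) -> "_NodeSeq":
        return _NodeSeq(self.seq.copy(), self.profile, self.rates,
                        list(self.cb), list(self.rep), dict(self.anchors))

    def _shift(self, p: int, delta: int) -> None:
        self.cb = [(k, s + delta if s > p else s,
                    e + delta if e > p else e) for k, s, e in self.cb]
        self.rep = [(u, s + delta if s > p else s,
                     e + delta if e > p else e) for u, s, e in self.rep]
        self.anchors = {n: a + delta if a > p else a
                        for n, a in self.anchors.items()}

    def apply_indels(self, rate: float, t: float, core_len: int,
                     rng: np.random.Generator) -> None:
        id_len = len(self.seq) - core_len
        if id_len <= 1:
            return
        n = rng.poisson(rate * id_len * t)
        for _ in range(n):
            id_len = len(self.seq) - core_len
            if id_len <= 1:
                return
            p = core_len + int(rng.integers(id_len))
            if rng.random() < 0.5:   # insertion before p
                letter = rng.choice(N_AA, p=self.profile[p])
                self.seq = np.insert(self.seq, p, letter)
                self.profile = np.insert(self.profile, p, self.profile[p],
                                         axis=0)
                self.rates = np.insert(self.rates, p, self.rates[p])
                self._shift(p, +1)
            else:                    # deletion of p
                self.seq = np.delete(self.seq, p)
                self.profile = np.delete(self.profile, p, axis=0)
                self.rates = np.delete(self.rates, p)
                self._shift(p, -1)


def _evolve(seq: np.ndarray, profiles: np.ndarray, rates: np.ndarray,
            t: float, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute along a branch of length ``t``.

    Each site is hit by a Poisson(rates[p] * t) number of substitution
    events; every hit resamples the residue i.i.d. from the site's profile,
    so the state after one or more hits is a single profile draw — the
    branch reduces to: with probability 1 - exp(-rate*t) resample the site.
    """
    seq = seq.copy()
    L = len(seq)
    if t <= 0 or L == 0:
        return seq
    p_hit = 1.0 - np.exp(-np.asarray(rates) * t)
    hits = np.flatnonzero(rng.random(L) < p_hit)
    for p in hits:
        seq[p] = rng.choice(N_AA, p=profiles[p])
    return seq


def generate_proteome(tree: Phylogeny, params: EvolParams,
                      characters: Mapping[str, Mapping[str, int]],
                      seed: int) -> tuple[dict[str, list[tuple[str, str]]],
                                          TruthBundle]:
    """Generate one proteome per leaf plus the full truth bundle.

    ``characters`` maps each motif name (matching ``params.motif_specs``) to
    its per-leaf 0/1 state.  The focal family protein in each genome is the
    evolved core + disordered region; a motif instance is written over the
    background residues at its anchor whenever the leaf state is 1, so the
    region's length distribution is independent of the character state.
    """
    rng = np.random.default_rng(seed)
    specs = {s.name: s for s in params.motif_specs}
    if set(characters) != set(specs):
        raise ValueError("characters must be indexed by the configured "
                         f"motif names {sorted(specs)}")

    # ancestral focal protein --------------------------------------------
    core_len = params.core_length
    id_len = max(60, int(round(rng.normal(params.id_length_mean,
                                          params.id_length_sd))))
    profiles = list(params.composition_profiles)
    k = len(profiles)
    bounds = [round(i * id_len / k) for i in range(k + 1)]
    anc_core = _draw_seq(rng, GLOBULAR_PROFILE, core_len)
    anc_id = np.concatenate([
        _draw_seq(rng, profiles[i], bounds[i + 1] - bounds[i])
        for i in range(k)]) if id_len else np.empty(0, dtype=int)
    # per-position substitution profile and rate: the disordered background
    # turns over much faster than the core; repeat tracks are maintained
    # (slow rate), emulating their continual regeneration
    pos_profile = np.empty((core_len + id_len, N_AA))
    pos_profile[:core_len] = GLOBULAR_PROFILE
    for i in range(k):
        pos_profile[core_len + bounds[i]:core_len + bounds[i + 1]] = profiles[i]
    pos_rates = np.full(core_len + id_len, params.id_substitution_rate)
    pos_rates[:core_len] = params.substitution_rate

    # repeat tracks replace background inside the ID region
    cb_truth = [(f"block{i + 1}", core_len + bounds[i] + 1,
                 core_len + bounds[i + 1]) for i in range(k)
                if bounds[i + 1] > bounds[i]]
    repeat_truth: list[tuple[str, int, int]] = []
    n_tr = len(params.repeat_tracks)
    for r, (unit, copies) in enumerate(params.repeat_tracks):
        track = seq_to_ints(unit * copies)
        if np.any(track < 0):
            raise ValueError(f"repeat unit {unit!r} has non-canonical letters")
        start = int(round((r + 1) / (n_tr + 1) * id_len)) - len(track) // 2
        start = max(0, min(start, id_len - len(track)))
        if len(track) > id_len:
            raise ValueError("repeat track longer than the disordered region")
        anc_id[start:start + len(track)] = track
        pos_rates[core_len + start:core_len + start + len(track)] = \
            params.substitution_rate
        repeat_truth.append((unit, core_len + start + 1,
                             core_len + start + len(track)))

    ancestor = np.concatenate([anc_core, anc_id])

    # motif anchor windows (absolute, 0-based start)
    anchors: dict[str, int] = {}
    occupied: list[tuple[int, int]] = []
    for name, spec in specs.items():
        w = spec.width
        if id_len < w:
            raise ValueError("disordered region shorter than motif width")
        start = core_len + int(round(spec.anchor * (id_len - w)))
        for s0, e0 in occupied:
            if start < e0 and start + w > s0:
                raise ValueError(
                    f"motif {name!r} anchor overlaps another motif; "
                    "space the anchors")
        occupied.append((start, start + w))
        anchors[name] = start

    # evolve along the tree ----------------------------------------------
    # per-node state: (sequence, per-site profile, per-site rate,
    # cb blocks, repeat segments, motif anchor starts) so that indels keep
    # every truth coordinate consistent
    root_state = _NodeSeq(ancestor, pos_profile, pos_rates,
                          [(kind, s - 1, e) for kind, s, e in cb_truth],
                          [(u, s - 1, e) for u, s, e in repeat_truth],
                          dict(anchors))
    nodes: dict[int, _NodeSeq] = {tree.root: root_state}
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        t = float(tree.lengths[v])
        st = nodes[p].copy()
        st.seq = _evolve(st.seq, st.profile, st.rates, t, rng)
        if params.indel_rate > 0:
            st.apply_indels(params.indel_rate, t, core_len, rng)
        nodes[v] = st

    # decoy families (shared across genomes, evolved on the same tree)
    decoy_anc = [_draw_seq(rng, GLOBULAR_PROFILE, params.decoy_length)
                 for _ in range(params.n_decoys)]
    decoy_prof = np.tile(GLOBULAR_PROFILE, (params.decoy_length, 1))
    decoy_rates = np.full(params.decoy_length, params.substitution_rate)
    decoys: dict[int, list[np.ndarray]] = {tree.root: decoy_anc}
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        decoys[v] = [_evolve(s, decoy_prof, decoy_rates,
                             float(tree.lengths[v]), rng)
                     for s in decoys[p]]

    # assemble leaf proteomes --------------------------------------------
    proteomes: dict[str, list[tuple[str, str]]] = {}
    family_of: dict[tuple[str, str], str] = {}
    motif_coords: dict[tuple[str, str, str], tuple[int, int]] = {}
    cb_segments: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    repeat_coords: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    core_end: dict[tuple[str, str], int] = {}
    manifest: dict[str, str] = {}

    for leaf in tree.leaf_labels:
        v = tree.index_of(leaf)
        genome = leaf
        manifest[genome] = leaf
        st = nodes[v]
        focal = st.seq.copy()
        for name, spec in specs.items():
            if characters[name].get(leaf, 0):
                inst = seq_to_ints(spec.sample(rng))
                s0 = min(st.anchors[name], len(focal) - spec.width)
                focal[s0:s0 + spec.width] = inst
                motif_coords[(genome, "rne", name)] = (s0 + 1, s0 + spec.width)
        records = [("rne", ints_to_seq(focal))]
        family_of[(genome, "rne")] = "focal"
        cb_segments[(genome, "rne")] = [(kind, s + 1, e)
                                        for kind, s, e in st.cb if e > s]
        repeat_coords[(genome, "rne")] = [(u, s + 1, e)
                                          for u, s, e in st.rep if e > s]
        core_end[(genome, "rne")] = core_len
        for j in range(params.n_paralogs):
            para = _evolve(st.seq, st.profile, st.rates,
                           params.paralog_divergence, rng)
            pid = f"rne_p{j + 1}"
            records.append((pid, ints_to_seq(para)))
            family_of[(genome, pid)] = "focal_paralog"
        for d in range(params.n_decoys):
            pid = f"dec{d + 1}"
            records.append((pid, ints_to_seq(decoys[v][d])))
            family_of[(genome, pid)] = f"decoy{d + 1}"
        proteomes[genome] = records

    chars = {name: SimulatedCharacter(dict(st), {}, [])
             if not isinstance(st, SimulatedCharacter) else st
             for name, st in characters.items()}
    bundle = TruthBundle(
        newick=tree.to_newick(), manifest=manifest, family_of=family_of,
        characters=chars, motif_coords=motif_coords, cb_segments=cb_segments,
        repeat_coords=repeat_coords, core_end=core_end,
        motif_specs=list(params.motif_specs))
    return proteomes, bundle


def simulate_dataset(params: EvolParams) -> tuple[
        Phylogeny, dict[str, list[tuple[str, str]]], TruthBundle]:
    """Sample a tree, evolve one character per configured motif, generate
    proteomes, and return (tree, proteomes, truth)."""
    tree = sample_tree(params.n_taxa, params.birth_rate, params.seed)
    rng = np.random.default_rng(params.seed + 1)
    characters: dict[str, SimulatedCharacter] = {}
    for spec in params.motif_specs:
        characters[spec.name] = simulate_binary_character(
            tree, params.gain_rate, params.loss_rate, params.root_state,
            int(rng.integers(0, 2**31 - 1)))
    proteomes, bundle = generate_proteome(
        tree, params, {n: c.leaf_states for n, c in characters.items()},
        params.seed + 2)
    bundle.characters = characters
    return tree, proteomes, bundle


def clade_gain_scenario(seed: int, n_taxa: int = 16,
                        motif_specs: Sequence[MotifSpec] | None = None,
                        min_clade: int = 4, min_stem: float = 0.4,
                        **param_overrides) -> tuple[
        Phylogeny, dict[str, list[tuple[str, str]]], TruthBundle,
        dict[str, str]]:
    """A dataset in which each configured motif was gained exactly once, on
    the stem of its own clade.

    Yule trees are sampled from ``seed`` (advancing deterministically) until
    one offers enough pairwise-disjoint clades — each with at least
    ``min_clade`` leaves, a stem branch of length >= ``min_stem`` (so the
    gain can localise), and not a child of the root (so outgroup context
    pins the root state).  Each motif's character is 1 exactly on its
    clade's leaves.  Returns (tree, proteomes, truth, motif -> stem node).
    """
    if motif_specs is None:
        motif_specs = [
            MotifSpec("alpha", "WQHKCMFDYWIHECM", anchor=0.25, noise=0.02),
            MotifSpec("beta", "LDGYFWPTNKRSVEQ", anchor=0.75, noise=0.02),
        ]
    need = len(motif_specs)
    root_kids_excluded = True
    for attempt in range(200):
        tree_seed = seed + attempt
        tree = sample_tree(n_taxa, 1.0, tree_seed)
        cand = []
        for i, lab in enumerate(tree.labels):
            if tree.is_leaf[i] or i == tree.root:
                continue
            if root_kids_excluded and i in tree.children[tree.root]:
                continue
            leaves = set(tree.leaves_under(i))
            if (len(leaves) >= min_clade and len(leaves) <= n_taxa - 3
                    and float(tree.lengths[i]) >= min_stem):
                cand.append((lab, leaves))
        # greedy disjoint selection, largest stems first
        cand.sort(key=lambda c: -float(tree.lengths[tree.index_of(c[0])]))
        chosen: list[tuple[str, set]] = []
        for lab, leaves in cand:
            if all(not (leaves & lv) for _, lv in chosen):
                chosen.append((lab, leaves))
            if len(chosen) == need:
                break
        if len(chosen) == need:
            break
    else:
        raise RuntimeError("no tree with enough disjoint clades found")
    stems = {spec.name: chosen[i][0] for i, spec in enumerate(motif_specs)}
    characters = {
        spec.name: {lab: int(lab in chosen[i][1])
                    for lab in tree.leaf_labels}
        for i, spec in enumerate(motif_specs)}
    params = EvolParams(n_taxa=n_taxa, seed=tree_seed,
                        motif_specs=list(motif_specs), **param_overrides)
    proteomes, bundle = generate_proteome(tree, params, characters,
                                          tree_seed + 1)
    return tree, proteomes, bundle, stems


# ---------------------------------------------------------------------------
# file output

def write_dataset(outdir: str | Path, tree: Phylogeny,
                  proteomes: dict[str, list[tuple[str, str]]],
                  bundle: TruthBundle) -> None:
    """Write FASTA per genome, the Newick tree, a genome manifest, the core
    boundary table and the truth bundle JSON."""
    out = Path(outdir)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    for genome in sorted(proteomes):
        with open(out / "proteomes" / f"{genome}.faa", "w") as fh:
            for pid, seq in proteomes[genome]:
                fh.write(f">{genome}|{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    (out / "species.nwk").write_text(tree.to_newick() + "\n")
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("genome\tspecies\n")
        for g in sorted(bundle.manifest):
            fh.write(f"{g}\t{bundle.manifest[g]}\n")
    with open(out / "core_boundaries.tsv", "w") as fh:
        fh.write("genome\tprotein\tcore_end\n")
        for (g, p) in sorted(bundle.core_end):
            fh.write(f"{g}\t{p}\t{bundle.core_end[(g, p)]}\n")
    (out / "truth.json").write_text(bundle.to_json() + "\n")
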