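"""ZOOPS motif discovery, PWM scanning, and the presence/absence matrix.

Short conserved motifs (width 10–25) are discovered in unaligned disordered
regions under the ZOOPS model — each sequence carries *zero or one*
occurrence of the motif.  The generative model: with probability
``gamma`` a sequence contains one motif instance at a uniformly chosen
position (emitted column-wise from the PWM); all other residues are i.i.d.
background.  Expectation–maximisation alternates a posterior over
{no site, site at j} per sequence with PWM/``gamma`` updates; discovered
occurrences are erased (masked) and discovery repeats for the next motif,
up to 30 motifs.

Annotation scans each sequence with the learned PWM (log-odds, bits) and
keeps at most the single best window per sequence above a score threshold;
the per-species presence/absence of every motif forms the binary matrix
consumed by ancestral reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alphabet import ALPHABET, N_AA, global_frequencies, seq_to_ints

__all__ = [
    "MotifModel", "MotifOccurrence", "ZoopsMotifDiscovery",
    "discover_motifs", "score_site", "scan_sequences", "presence_matrix",
    "write_meme_minimal", "read_meme_minimal",
]


# ---------------------------------------------------------------------------
# model containers

@dataclass
class MotifModel:
    """A learned motif: PWM + background + ZOOPS site prior."""

    pwm: np.ndarray                  # (width, 20), columns sum to 1
    background: np.ndarray           # (20,)
    gamma: float                     # P(a sequence contains the motif)
    rank: int = 0
    name: str = ""
    llr: float = 0.0                 # ZOOPS log-likelihood ratio vs background

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        w = self.width
        if not 10 <= w <= 25:
            raise ValueError(f"motif width must be in [10, 25], got {w}")
        if np.any(np.abs(self.pwm.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.pwm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 20) log2(pwm / background)."""
        return np.log2(self.pwm / self.background[None, :])

    def information_content(self) -> float:
        """Total relative entropy of the PWM vs background, in bits."""
        lo = self.log_odds()
        return float(np.sum(self.pwm * lo))

    def max_score(self) -> float:
        """Best attainable log-odds score, in bits."""
        return float(self.log_odds().max(axis=1).sum())

    def significance(self, n_seqs: int) -> float:
        """Ranking surrogate: information content (bits) x expected number
        of sites (gamma * n_seqs)."""
        return self.information_content() * self.gamma * n_seqs


@dataclass(frozen=True)
class MotifOccurrence:
    genome: str
    protein: str
    motif: str
    start: int          # 1-based
    score: float        # log-odds, bits
    site_prob: float = 1.0


# ---------------------------------------------------------------------------
# ZOOPS EM

def _window_view(ix: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """(m, w) integer windows and a validity mask (no masked residue)."""
    if len(ix) < w:
        return np.empty((0, w), dtype=int), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(ix, w)
    return win, ~np.any(win < 0, axis=1)


def _seq_log_bg(ix: np.ndarray, log_bg: np.ndarray) -> float:
    ok = ix >= 0
    return float(log_bg[ix[ok]].sum())


class _ZoopsState:
    """Per-width precomputation shared by all EM iterations.

    All valid windows of all sequences are flattened into one (N, w)
    integer matrix; per-sequence reductions use ``reduceat`` over segment
    offsets so each EM sweep is a handful of vectorised operations.
    """

    def __init__(self, seq_ints: Sequence[np.ndarray], w: int,
                 background: np.ndarray):
        self.w = w
        self.background = background
        self.log_bg = np.log(background)
        self.n_seqs = len(seq_ints)
        flat, counts = [], []
        self.logp0 = 0.0
        for ix in seq_ints:
            win, ok = _window_view(ix, w)
            flat.append(win[ok])
            counts.append(int(ok.sum()))
            self.logp0 += _seq_log_bg(ix, self.log_bg)
        nwin = np.array(counts)
        keep = nwin > 0
        self.windows = (np.concatenate([f for f in flat if len(f)])
                        if keep.any() else np.empty((0, w), dtype=int))
        self.nwin = nwin[keep]
        self.offsets = np.concatenate([[0], np.cumsum(self.nwin)[:-1]])
        self.seq_id = np.repeat(np.arange(len(self.nwin)), self.nwin)
        self.cols = np.arange(w)[None, :]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def _e_step(self, pwm: np.ndarray, gamma: float
                ) -> tuple[np.ndarray, float]:
        """Per-window site posteriors and the data log-likelihood ratio."""
        log_ratio = np.log(pwm) - self.log_bg[None, :]
        t = log_ratio[self.cols, self.windows].sum(axis=1)
        t += np.log(gamma) - np.log(self.nwin)[self.seq_id]
        a0 = np.log1p(-gamma) if gamma < 1 else -np.inf
        mx = np.maximum(np.maximum.reduceat(t, self.offsets), a0)
        ez = np.exp(t - mx[self.seq_id])
        sums = np.add.reduceat(ez, self.offsets) + np.exp(a0 - mx)
        llr = float(np.sum(mx + np.log(sums)))
        z = ez / sums[self.seq_id]
        return z, llr

    def em(self, pwm0: np.ndarray, gamma0: float, pseudocount: float,
           tol: float, max_iter: int
           ) -> tuple[np.ndarray, float, float, list[float]]:
        """Run EM to convergence.

        Returns (pwm, gamma, data_llr, objective_trace).  ``data_llr`` is the
        ZOOPS log likelihood minus the all-background log likelihood; the
        trace is the Dirichlet-penalised objective (the quantity the MAP
        M-step makes non-decreasing), one entry per iteration.
        """
        w = self.w
        if self.n_windows == 0:
            return pwm0.copy(), float(gamma0), -np.inf, [-np.inf]
        pwm = pwm0.copy()
        gamma = float(gamma0)
        trace: list[float] = []
        llr = -np.inf
        for _ in range(max_iter):
            z, llr_new = self._e_step(pwm, gamma)
            # penalised objective = data LLR + Dirichlet(1 + pc) log prior
            obj = llr_new + pseudocount * np.sum(np.log(pwm))
            trace.append(obj)
            # M-step (MAP with symmetric Dirichlet prior)
            counts = np.empty((w, N_AA))
            for j in range(w):
                counts[j] = np.bincount(self.windows[:, j], weights=z,
                                        minlength=N_AA)
            pwm = counts + pseudocount
            pwm /= pwm.sum(axis=1, keepdims=True)
            gamma = min(1.0 - 1e-9, max(1e-9, float(z.sum()) / self.n_seqs))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (
                    1.0 + abs(trace[-2])):
                llr = llr_new
                break
            llr = llr_new
        return pwm, gamma, llr, trace


def _seed_pwm(window: np.ndarray, self_weight: float = 0.8) -> np.ndarray:
    w = len(window)
    pwm = np.full((w, N_AA), (1.0 - self_weight) / (N_AA - 1))
    pwm[np.arange(w), window] = self_weight
    return pwm


class ZoopsMotifDiscovery(BaseEstimator):
    """Sequential ZOOPS motif discovery as an sklearn-style estimator.

    Parameters
    ----------
    w_min, w_max : int, defaults 10 and 25
        Motif width range.  Widths are searched coarsely
        (10, 13, 16, 19, 22, 25 clipped to the range) and the best width is
        refined by +/-1.
    n_motifs : int, default 30
        Maximum number of motifs to discover sequentially.
    n_seeds : int, default 60
        Number of data-derived starting subsequences evaluated per width
        (evenly spaced over all valid windows; each seeds a PWM with weight
        0.5 on its own letters, refined by 2 preliminary EM sweeps before
        the best seed gets the full EM).
    pseudocount : float, default 0.01
        Dirichlet smoothing added per residue per column in the M-step.
    min_significance : float, default 50.0
        Discovery stops early when a motif's ranking score (information
        content x expected site count) falls below this floor.
    min_sites : float, default 2.0
        Discovery also stops when the expected site count drops below this.
    tol : float, default 1e-6
        Relative convergence threshold on the EM objective.
    max_iter : int, default 200
    seed : int, default 0

    Attributes
    ----------
    motifs_ : list of MotifModel, ranked by significance (rank 1 first).
    objective_traces_ : list of per-iteration EM objective values, one per
        discovered motif (final EM run), each non-decreasing.
    background_ : ndarray (20,), background frequencies used.
    """

    _COARSE = (10, 13, 16, 19, 22, 25)

    def __init__(self, w_min: int = 10, w_max: int = 25, n_motifs: int = 30,
                 n_seeds: int = 60, pseudocount: float = 0.01,
                 min_significance: float = 50.0, min_sites: float = 2.0,
                 tol: float = 1e-6, max_iter: int = 200, seed: int = 0):
        self.w_min = w_min
        self.w_max = w_max
        self.n_motifs = n_motifs
        self.n_seeds = n_seeds
        self.pseudocount = pseudocount
        self.min_significance = min_significance
        self.min_sites = min_sites
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, X: Sequence[str], y=None) -> "ZoopsMotifDiscovery":
        """Discover motifs in a list of unaligned protein sequences."""
        if not 10 <= self.w_min <= self.w_max <= 25:
            raise ValueError("need 10 <= w_min <= w_max <= 25")
        seqs = [s.upper() for s in X]
        keep = [i for i, s in enumerate(seqs) if len(s) >= self.w_min]
        if len(keep) < len(seqs):
            warnings.warn(f"{len(seqs) - len(keep)} sequence(s) shorter than "
                          f"w_min={self.w_min} excluded from discovery")
        if len(keep) < 2:
            raise ValueError("need at least 2 sequences of length >= w_min")
        seq_ints = [seq_to_ints(seqs[i]) for i in keep]
        self.background_ = global_frequencies([seqs[i] for i in keep])
        self.kept_indices_ = keep

        widths = sorted({w for w in self._COARSE
                         if self.w_min <= w <= self.w_max} or {self.w_min})
        motifs: list[MotifModel] = []
        traces: list[list[float]] = []
        for _ in range(self.n_motifs):
            found = self._discover_one(seq_ints, widths)
            if found is None:
                break
            motif, trace = found
            n = len(seq_ints)
            if (motif.gamma * n < self.min_sites
                    or motif.significance(n) < self.min_significance):
                break
            motifs.append(motif)
            traces.append(trace)
            self._erase(seq_ints, motif)
        # rank by significance
        order = sorted(range(len(motifs)),
                       key=lambda i: -motifs[i].significance(len(seq_ints)))
        self.motifs_ = []
        self.objective_traces_ = []
        for rank, i in enumerate(order, start=1):
            motifs[i].rank = rank
            if not motifs[i].name:
                motifs[i].name = f"motif{rank}"
            self.motifs_.append(motifs[i])
            self.objective_traces_.append(traces[i])
        return self

    # ------------------------------------------------------------------
    def _discover_one(self, seq_ints, coarse_widths
                      ) -> tuple[MotifModel, list[float]] | None:
        best = None  # (penalized_llr, llr, w, pwm, gamma, trace)
        n = len(seq_ints)
        tried: set[int] = set()

        def penalized(llr: float, w: int, gamma: float) -> float:
            # BIC-style width penalty: comparing ZOOPS LLRs across widths
            # is otherwise biased toward wide motifs, whose extra columns
            # overfit the site sample (19 free frequencies per column).
            return llr - 0.5 * 19 * w * np.log(max(2.0, gamma * n))

        def run_width(w: int, extra_seeds: list[np.ndarray] = ()):
            nonlocal best
            tried.add(w)
            state = _ZoopsState(seq_ints, w, self.background_)
            seeds = [_seed_pwm(win) for win in self._seed_windows(state)]
            seeds.extend(extra_seeds)
            if not seeds:
                return
            # preliminary 2-sweep scoring of each seed
            scored = []
            for pwm0 in seeds:
                pwm, gamma, llr, _ = state.em(pwm0, 0.5, self.pseudocount,
                                              self.tol, 2)
                scored.append((llr, pwm, gamma))
            llr0, pwm0, gamma0 = max(scored, key=lambda t: t[0])
            pwm, gamma, llr, trace = state.em(pwm0, gamma0, self.pseudocount,
                                              self.tol, self.max_iter)
            score = penalized(llr, w, gamma)
            if best is None or score > best[0]:
                best = (score, llr, w, pwm, gamma, trace)

        def resized_seeds(pwm: np.ndarray, w: int) -> list[np.ndarray]:
            """Seeds for width w derived from a width w+/-1 PWM by trimming
            an edge column or padding with a background column."""
            cur = pwm.shape[0]
            if w == cur - 1:
                return [pwm[1:].copy(), pwm[:-1].copy()]
            if w == cur + 1:
                bgrow = self.background_[None, :]
                return [np.vstack([bgrow, pwm]), np.vstack([pwm, bgrow])]
            return []

        for w in coarse_widths:
            run_width(w)
        if best is None:
            return None
        # hill-climb width refinement around the best width, reusing the
        # locked-in alignment (resized PWM) as an extra seed
        improved = True
        while improved:
            here = best[2]
            for w in (here - 1, here + 1):
                if self.w_min <= w <= self.w_max:
                    run_width(w, resized_seeds(best[3], w))
            improved = best[2] != here
        _, llr, w, pwm, gamma, trace = best
        if llr <= 0:
            return None
        motif = MotifModel(pwm=pwm, background=self.background_,
                           gamma=gamma, llr=float(llr))
        return motif, trace

    def _seed_windows(self, state: _ZoopsState) -> list[np.ndarray]:
        allw = state.windows
        if len(allw) <= self.n_seeds:
            return list(allw)
        pick = np.linspace(0, len(allw) - 1, self.n_seeds).round().astype(int)
        return list(allw[np.unique(pick)])

    def _erase(self, seq_ints: list[np.ndarray], motif: MotifModel) -> None:
        """Mask (in place) every occurrence of a discovered motif.

        All non-overlapping windows with log-odds >= 60% of the maximum
        attainable score are masked, best first (repeat-derived motifs
        occur many times per sequence, so erasing a single site per
        sequence would let the same motif be rediscovered indefinitely).
        Masked residues are excluded from all later counting; coordinates
        are preserved.
        """
        w = motif.width
        lo = motif.log_odds()
        thresh = 0.6 * motif.max_score()
        for ix in seq_ints:
            win, ok = _window_view(ix, w)
            if not ok.any():
                continue
            pos = np.flatnonzero(ok)
            scores = lo[np.arange(w)[None, :], win[ok]].sum(axis=1)
            order = pos[np.argsort(-scores, kind="stable")]
            good = dict(zip(pos, scores))
            taken: list[int] = []
            for p in order:
                if good[p] < thresh:
                    break
                if all(abs(p - q) >= w for q in taken):
                    taken.append(int(p))
            for p in taken:
                ix[p:p + w] = -1

    # ------------------------------------------------------------------
    def transform(self, X: Sequence[str]) -> list[list["MotifOccurrence"]]:
        """Scan sequences with every discovered motif (ZOOPS annotation)."""
        return [scan_sequences(m, X) for m in self.motifs_]


# ---------------------------------------------------------------------------
# functional wrappers

def discover_motifs(seqs: Sequence[str], w_min: int = 10, w_max: int = 25,
                    n_motifs: int = 30, seed: int = 0, **kwargs
                    ) -> list[MotifModel]:
    """Thin wrapper over :class:`ZoopsMotifDiscovery`."""
    est = ZoopsMotifDiscovery(w_min=w_min, w_max=w_max, n_motifs=n_motifs,
                              seed=seed, **kwargs).fit(seqs)
    return est.motifs_


def score_site(motif: MotifModel, site: str) -> float:
    """Log-odds score of a width-w site against the motif, in bits."""
    if len(site) != motif.width:
        raise ValueError(f"site length {len(site)} != motif width "
                         f"{motif.width}")
    lo = motif.log_odds()
    total = 0.0
    for j, c in enumerate(site.upper()):
        i = ALPHABET.find(c)
        if i < 0:
            raise ValueError(f"non-canonical residue {c!r} in site")
        total += lo[j, i]
    return float(total)


def scan_sequences(motif: MotifModel, seqs, min_bits: float | None = None,
                   ids: Sequence[tuple[str, str]] | None = None
                   ) -> list[MotifOccurrence]:
    """Best-scoring window per sequence, reported iff >= ``min_bits``
    (default 60% of the motif's maximum attainable score).  At most one
    occurrence per sequence; ties resolved to the leftmost window.

    ``seqs`` may be a list of strings (ids default to their indices) or a
    mapping supplied via ``ids`` as (genome, protein) pairs.
    """
    if min_bits is None:
        min_bits = 0.6 * motif.max_score()
    if not np.isfinite(min_bits):
        raise ValueError("min_bits must be finite")
    lo = motif.log_odds()
    w = motif.width
    out: list[MotifOccurrence] = []
    for i, seq in enumerate(seqs):
        genome, protein = (ids[i] if ids is not None else ("", str(i)))
        ix = seq_to_ints(seq.upper())
        win, ok = _window_view(ix, w)
        if not ok.any():
            if len(seq) < w:
                warnings.warn(f"sequence {protein!r} shorter than motif "
                              f"width {w}: no occurrence")
            continue
        scores = lo[np.arange(w)[None, :], win[ok]].sum(axis=1)
        j = int(np.argmax(scores))          # argmax -> leftmost tie
        if scores[j] >= min_bits:
            pos = int(np.flatnonzero(ok)[j])
            out.append(MotifOccurrence(genome, protein,
                                       motif.name or f"motif{motif.rank}",
                                       pos + 1, float(scores[j])))
    return out


def presence_matrix(occurrences: Iterable[MotifOccurrence],
                    manifest: Mapping[str, str],
                    motif_names: Sequence[str] | None = None,
                    one_strain_per_species: bool = True) -> pd.DataFrame:
    """Binary motifs x species matrix.

    With ``one_strain_per_species`` the retained strain of each species is
    the lexicographically first genome id; occurrences in other strains are
    ignored.
    """
    occurrences = list(occurrences)
    for o in occurrences:
        if o.genome not in manifest:
            raise ValueError(f"genome {o.genome!r} missing from manifest")
    species = sorted(set(manifest.values()))
    strains: dict[str, list[str]] = {}
    for g in sorted(manifest):
        strains.setdefault(manifest[g], []).append(g)
    retained = {sp: (gs[0] if one_strain_per_species else None)
                for sp, gs in strains.items()}
    if motif_names is None:
        motif_names = sorted({o.motif for o in occurrences})
    mat = pd.DataFrame(0, index=list(motif_names), columns=species,
                       dtype=int)
    for o in occurrences:
        sp = manifest[o.genome]
        if one_strain_per_species and o.genome != retained[sp]:
            continue
        if o.motif in mat.index:
            mat.loc[o.motif, sp] = 1
    return mat


# ---------------------------------------------------------------------------
# MEME minimal text format

def write_meme_minimal(motifs: Sequence[MotifModel], path: str | Path
                       ) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + ALPHABET + "\n\n")
        fh.write("Background letter frequencies\n")
        if motifs:
            bg = motifs[0].background
        else:
            bg = np.full(N_AA, 1.0 / N_AA)
        fh.write(" ".join(f"{a} {f:.6f}" for a, f in zip(ALPHABET, bg))
                 + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name or ('motif%d' % m.rank)} {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= {N_AA} "
                     f"w= {m.width} nsites= {max(1, round(m.gamma * 100))} "
                     f"E= 0\n")
            for row in m.pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme_minimal(path: str | Path) -> list[MotifModel]:
    text = Path(path).read_text().splitlines()
    bg = np.full(N_AA, 1.0 / N_AA)
    motifs: list[MotifModel] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = text[i + 1].split()
            bg = np.array([float(parts[2 * j + 1]) for j in range(N_AA)])
            i += 2
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            header = text[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(x) for x in text[i].split()])
            pwm = np.array(rows)
            pwm /= pwm.sum(axis=1, keepdims=True)
            motifs.append(MotifModel(pwm=pwm, background=bg, gamma=1.0,
                                     name=name, rank=len(motifs) + 1))
            i += 1
        else:
            i += 1
    return motifs
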