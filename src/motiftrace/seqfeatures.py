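"""Hallmarks of the disordered noncatalytic region.

Annotates the features that characterise the region downstream of the
catalytic core: composition-biased (CB) segments called by an exact
binomial-tail test against background residue frequencies; tandem repeats
of short units; amphipathic-helix candidates via the hydrophobic moment;
fixed sequence patterns (e.g. the CPxCxGxG Zn-link); and a lightweight
charge–hydropathy disorder index.  All coordinates are 1-based inclusive.

The disorder index is a simple heuristic defined here (a linear function of
windowed Kyte–Doolittle hydropathy and net charge); it is NOT equivalent to
a machine-learned disorder predictor and is labelled as a heuristic in all
outputs (feature kind ``disorder_heuristic``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .alphabet import AA_INDEX, ALPHABET, N_AA

__all__ = [
    "Segment", "lps_scan", "cluster_cb_segments", "find_tandem_repeats",
    "hydrophobic_moment", "disorder_index", "pattern_scan",
    "extract_noncatalytic", "composition_profile",
]


@dataclass
class Segment:
    """An annotated stretch of one protein (1-based inclusive coords)."""

    protein: str
    start: int
    end: int
    kind: str
    score: float
    signature: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad segment coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# composition bias

def lps_scan(seq: str, background: Mapping[str, float] | np.ndarray,
             p_max: float = 1e-15, min_len: int = 5, max_len: int = 500,
             protein: str = "?") -> list[Segment]:
    """Low-probability composition-biased segments.

    For every residue type ``r`` and every window of length ``min_len`` to
    ``max_len``, the binomial tail P(X >= k) is computed with n = window
    length, p = background frequency of ``r``, k = count of ``r`` in the
    window.  Windows with tail probability <= ``p_max`` are reported;
    overlapping windows for the same residue are resolved to the
    lowest-probability one (ties to the longer, then leftmost, window).
    The reported score is the tail probability.
    """
    if min_len > max_len or min_len < 1:
        raise ValueError("window bounds inconsistent")
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    bg = _background_vector(background)
    ix = np.array([AA_INDEX.get(c, -1) for c in seq.upper()])
    n = len(ix)
    segments: list[Segment] = []
    for r in range(N_AA):
        p = float(bg[r])
        if p <= 0 or p >= 1 or not np.any(ix == r):
            continue
        pref = np.concatenate([[0], np.cumsum(ix == r)])
        cands: list[tuple[float, int, int]] = []
        Ls = np.arange(min_len, min(max_len, n) + 1)
        # smallest count that can reach p_max at each window length
        # (conservative by one unit against isf discretisation)
        kmin = np.maximum(stats.binom.isf(p_max, Ls, p) - 1, 1)
        for L, km in zip(Ls, kmin):
            k = pref[L:] - pref[:-L]          # count of r in each window
            starts = np.flatnonzero(k >= km)
            if len(starts) == 0:
                continue
            tails = stats.binom.sf(k[starts] - 1, L, p)
            hit = tails <= p_max
            for s, t in zip(starts[hit], tails[hit]):
                cands.append((float(t), int(s), int(s + L - 1)))
        # greedy resolution: lowest probability first, longer then leftmost
        cands.sort(key=lambda c: (c[0], -(c[2] - c[1]), c[1]))
        taken: list[tuple[int, int]] = []
        for t, s, e in cands:
            if all(e < s0 or s > e0 for s0, e0 in taken):
                taken.append((s, e))
                segments.append(Segment(protein, s + 1, e + 1,
                                        "composition_bias", t, ALPHABET[r]))
    segments.sort(key=lambda g: (g.start, g.end, g.signature))
    return segments


def composition_profile(seq: str) -> np.ndarray:
    """Residue frequencies of a segment (length-20 vector summing to 1)."""
    ix = np.array([AA_INDEX[c] for c in seq.upper() if c in AA_INDEX])
    if len(ix) == 0:
        raise ValueError("segment contains no canonical residues")
    return np.bincount(ix, minlength=N_AA) / len(ix)


def cluster_cb_segments(profiles: Sequence[np.ndarray], k: int, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """k-means grouping of composition profiles (Euclidean distance).

    Returns (labels, centroids); centroids are frequency vectors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("profiles must be a nonempty list of vectors")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(X)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return km.labels_.copy(), km.cluster_centers_.copy()


# ---------------------------------------------------------------------------
# tandem repeats

def _repeat_candidates(ix: np.ndarray, p: int, min_copies: int,
                       min_identity: float) -> list[tuple[int, int, int, int]]:
    """All (start, end, period, matches) windows with >= min_copies*p
    residues and column identity >= min_identity for period p.  end is
    inclusive; matches counts positions i in [start, end-p] with
    seq[i] == seq[i+p]."""
    n = len(ix)
    min_len = min_copies * p
    if n < min_len:
        return []
    m = (ix[:-p] == ix[p:]).astype(int)
    pref = np.concatenate([[0], np.cumsum(m)])
    out = []
    for L in range(min_len, n + 1):
        ncol = L - p
        need = min_identity * ncol
        starts = np.arange(0, n - L + 1)
        matches = pref[starts + ncol] - pref[starts]
        ok = np.flatnonzero(matches >= need - 1e-12)
        for s in ok:
            out.append((int(s), int(s + L - 1), p, int(matches[s])))
    return out


def _consensus_unit(seq: str, start: int, end: int, p: int) -> str:
    cols: list[str] = []
    for j in range(p):
        letters = [seq[i] for i in range(start + j, end + 1, p)]
        best = max(sorted(set(letters)), key=letters.count)
        cols.append(best)
    return "".join(cols)


def find_tandem_repeats(seq: str, min_period: int = 3, max_period: int = 10,
                        min_copies: int = 3, min_identity: float = 0.9,
                        protein: str = "?") -> list[Segment]:
    """Tandem repeats: maximal regions where ``seq[i] == seq[i+p]`` for some
    period ``p``, with column identity >= ``min_identity`` over at least
    ``min_copies * p`` residues.

    Overlapping candidate calls are resolved greedily to the call with the
    most matching columns (ties: smaller period, then leftmost).  The
    segment's score is the (possibly fractional) copy number; its signature
    is the majority-consensus unit.
    """
    if not 1 <= min_period <= max_period:
        raise ValueError("need 1 <= min_period <= max_period")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    ix = np.array([AA_INDEX.get(c, -1) for c in seq.upper()])
    cands: list[tuple[int, int, int, int]] = []
    for p in range(min_period, min(max_period, max(1, len(ix) - 1)) + 1):
        cands.extend(_repeat_candidates(ix, p, min_copies, min_identity))
    cands.sort(key=lambda c: (-c[3], c[2], c[0], -(c[1] - c[0])))
    taken: list[tuple[int, int]] = []
    out: list[Segment] = []
    for s, e, p, match in cands:
        if any(not (e < s0 or s > e0) for s0, e0 in taken):
            continue
        taken.append((s, e))
        copies = (e - s + 1) / p
        out.append(Segment(protein, s + 1, e + 1, "tandem_repeat",
                           round(copies, 6), _consensus_unit(seq, s, e, p)))
    out.sort(key=lambda g: g.start)
    return out


# ---------------------------------------------------------------------------
# hydrophobic moment & disorder heuristic

#: Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def hydrophobic_moment(window: str, delta: float = 100.0,
                       scale: Mapping[str, float] | None = None) -> float:
    """Mean-vector hydrophobic moment of a window, per residue.

    mu_H = | sum_n H(r_n) * exp(i * n * delta) | / L with ``delta`` in
    degrees (100 for an alpha helix) and the Eisenberg consensus scale by
    default.  Unknown residues contribute 0 (with a warning).
    """
    if len(window) < 2:
        raise ValueError("window must have length >= 2")
    if scale is None:
        scale = EISENBERG
    h = []
    for c in window.upper():
        if c not in scale:
            import warnings
            warnings.warn(f"unknown residue {c!r} treated as hydrophobicity 0")
            h.append(0.0)
        else:
            h.append(scale[c])
    n = np.arange(len(h))
    phase = np.deg2rad(delta) * n
    vec = np.sum(np.asarray(h) * np.exp(1j * phase))
    return float(np.abs(vec)) / len(h)


def disorder_index(seq: str, window: int = 21) -> np.ndarray:
    """Per-residue disorder heuristic (negative = predicted disordered).

    index = 2.785 * <H_norm> - |<q>| - 1.151 over a centred window
    (truncated at the edges), with H_norm = (Kyte-Doolittle + 4.5) / 9 and
    q the net charge (K, R: +1; D, E: -1).  A charge-hydropathy heuristic,
    not a trained disorder predictor.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    s = seq.upper()
    h = np.array([(KYTE_DOOLITTLE.get(c, 0.0) + 4.5) / 9.0 for c in s])
    q = np.array([_CHARGE.get(c, 0.0) for c in s])
    half = window // 2
    n = len(s)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = 2.785 * h[lo:hi].mean() - abs(q[lo:hi].mean()) - 1.151
    return out


# ---------------------------------------------------------------------------
# patterns & region extraction

def pattern_scan(seq: str, pattern: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) matches of a
    fixed/wildcard pattern such as ``CPxCxGxG`` (``x`` matches any residue)."""
    if not pattern:
        raise ValueError("pattern must be nonempty")
    rx = "".join("." if c in "xX" else re.escape(c.upper()) for c in pattern)
    return [m.start() + 1
            for m in re.finditer(f"(?=({rx}))", seq.upper())]


def extract_noncatalytic(seq: str, core_end: int) -> str:
    """Residues core_end+1 .. end (1-based inclusive); core_end = 0 returns
    the whole sequence."""
    if not 0 <= core_end < len(seq):
        raise ValueError(f"core_end={core_end} outside sequence of length "
                         f"{len(seq)}")
    return seq[core_end:]


def write_features_tsv(segments: Sequence[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tkind\tstart\tend\tscore\tsignature\n")
        for s in segments:
            fh.write(f"{s.protein}\t{s.kind}\t{s.start}\t{s.end}\t"
                     f"{s.score!r}\t{s.signature}\n")


def read_features_tsv(path) -> list[Segment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("protein\t")
        for line in fh:
            prot, kind, start, end, score, sig = line.rstrip("\n").split("\t")
            out.append(Segment(prot, int(start), int(end), kind,
                               float(score), sig))
    return out


def _background_vector(background: Mapping[str, float] | np.ndarray
                       ) -> np.ndarray:
    if isinstance(background, np.ndarray):
        v = background.astype(float)
    else:
        v = np.zeros(N_AA)
        for a, f in background.items():
            v[AA_INDEX[a]] = f
    if abs(float(v.sum()) - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    return v
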