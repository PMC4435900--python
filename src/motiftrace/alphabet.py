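"""Amino-acid alphabet, index maps and canonical composition profiles."""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
N_AA = len(ALPHABET)

#: Symbol used to mask residues (erased motif occurrences, unknowns).
MASK = "X"

# Average composition of globular bacterial proteins (Robinson & Robinson
# style frequencies, renormalised over the 20 canonical letters).  Used for
# catalytic cores and decoy proteins.
GLOBULAR_FREQS = {
    "A": 0.078, "C": 0.019, "D": 0.053, "E": 0.063, "F": 0.039,
    "G": 0.072, "H": 0.022, "I": 0.053, "K": 0.059, "L": 0.091,
    "M": 0.022, "N": 0.043, "P": 0.052, "Q": 0.042, "R": 0.051,
    "S": 0.068, "T": 0.059, "V": 0.066, "W": 0.014, "Y": 0.032,
}

# Residues systematically depleted in the disordered region.
_DEPLETED = set("WFYCLMH")


def as_vector(freqs: dict[str, float]) -> np.ndarray:
    """Dict of residue frequencies -> length-20 vector summing to 1."""
    v = np.zeros(N_AA)
    for a, f in freqs.items():
        v[AA_INDEX[a]] = f
    s = v.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValueError("frequencies must sum to a positive value")
    return v / s


def _biased_profile(named: dict[str, float]) -> np.ndarray:
    """Profile with the stated enriched residues; the remaining mass is
    spread over the other letters, down-weighting order-promoting residues
    (W, F, Y, C, L, M, H) fivefold."""
    v = np.zeros(N_AA)
    for a, f in named.items():
        v[AA_INDEX[a]] = f
    rest = 1.0 - v.sum()
    if rest < 0:
        raise ValueError("named frequencies exceed 1")
    w = np.array([0.0 if a in named else (0.2 if a in _DEPLETED else 1.0)
                  for a in ALPHABET])
    v += rest * w / w.sum()
    return v


#: RNQ-rich disorder profile (R 0.214, N 0.101, Q 0.091).
RNQ_PROFILE = _biased_profile({"R": 0.214, "N": 0.101, "Q": 0.091})

#: AEPV-rich disorder profile (A 0.208, E 0.138, P 0.106, V 0.127).
AEPV_PROFILE = _biased_profile({"A": 0.208, "E": 0.138, "P": 0.106, "V": 0.127})

GLOBULAR_PROFILE = as_vector(GLOBULAR_FREQS)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a sequence as indices into ALPHABET; MASK/unknown -> -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def ints_to_seq(ix: np.ndarray) -> str:
    return "".join(ALPHABET[i] if i >= 0 else MASK for i in ix)


def global_frequencies(seqs) -> np.ndarray:
    """Overall residue frequencies of an iterable of sequences
    (masked/unknown letters ignored), with a small floor so that no
    frequency is exactly zero."""
    counts = np.zeros(N_AA)
    for s in seqs:
        ix = seq_to_ints(s)
        ix = ix[ix >= 0]
        counts += np.bincount(ix, minlength=N_AA)
    counts += 0.1
    return counts / counts.sum()
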