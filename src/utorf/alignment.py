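"""Zero-gap-penalty Smith–Waterman protein scoring.

The score is a local alignment under BLOSUM62 with gap open and extension
penalties of zero. With free gaps the optimum is a maximum-scoring chain of
residue pairs with strictly increasing indices in both sequences, which makes
the dynamic program a 2-D prefix-maximum recurrence:

    D[i, j]   = max(0, s(a_i, b_j) + P[i-1, j-1])
    P[i, j]   = max over i' <= i, j' <= j of D[i', j']

and the raw score is the maximum D. Stop codons translate to '*' and score -4
(the BLOSUM62 minimum) against everything — they never terminate the
alignment, which tolerates recent nonsense or frameshift mutations in the
scored species.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
STOP_SCORE = -4.0


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense float matrix over ``ALPHABET``, with every pair
    involving '*' set to -4 (a stop is not a residue)."""
    raw = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "*" or b == "*":
                mat[i, j] = STOP_SCORE
            else:
                mat[i, j] = raw[a][b]
    return mat


_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def encode(aa: str) -> np.ndarray:
    """Encode an amino-acid string (may include '*' and ambiguity codes) to
    matrix indices."""
    try:
        return np.fromiter((_INDEX[c] for c in aa), dtype=np.intp, count=len(aa))
    except KeyError as e:
        raise ValueError(f"symbol {e.args[0]!r} not scoreable") from None


def zero_gap_local_score(a: str, b: str) -> float:
    """Raw (unnormalized) zero-gap local alignment score of two amino-acid
    strings; 0.0 for empty inputs."""
    if not a or not b:
        return 0.0
    ai = encode(a)
    bi = encode(b)
    S = blosum62_matrix()
    m = len(bi)
    # P[j] = max D over all rows processed so far and columns <= j.
    P = np.zeros(m)
    best = 0.0
    sub = S[ai][:, bi]  # len(a) x len(b) pair scores
    for row in sub:
        prev = np.empty(m)
        prev[0] = 0.0
        prev[1:] = P[:-1]
        D = np.maximum(row + prev, 0.0)
        np.maximum.accumulate(D, out=D)
        np.maximum(P, D, out=P)
    best = float(P[-1])
    return best


def self_score(aa: str) -> float:
    """Diagonal BLOSUM62 score of a sequence against itself (upper bound of
    the local alignment)."""
    S = blosum62_matrix()
    idx = encode(aa)
    return float(S[idx, idx].sum())
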