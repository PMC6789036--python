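"""Shared amino-acid alphabet, background frequencies and scoring matrices.

The 20-letter alphabet is ordered alphabetically by one-letter code; 'X'
denotes an unknown residue and is handled by the consumers (background
emission in profile scoring, mismatch in identity counting).
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

# Robinson & Robinson (1991) amino-acid frequencies, the conventional i.i.d.
# null model for protein profile search; renormalized to sum exactly to 1.
_RR = {
    "A": 0.0787945, "C": 0.0151600, "D": 0.0535222, "E": 0.0668298,
    "F": 0.0397062, "G": 0.0695071, "H": 0.0229198, "I": 0.0590092,
    "K": 0.0594422, "L": 0.0963728, "M": 0.0237718, "N": 0.0414386,
    "P": 0.0481970, "Q": 0.0325690, "R": 0.0512495, "S": 0.0682469,
    "T": 0.0585148, "V": 0.0673417, "W": 0.0114135, "Y": 0.0304133,
}

BACKGROUND = np.array([_RR[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()


@functools.cache
def blosum62() -> np.ndarray:
    """BLOSUM62 scores as a 20x20 array in AMINO_ACIDS order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


@functools.cache
def substitution_probs() -> np.ndarray:
    """Conditional substitution probabilities P(b | a) derived from BLOSUM62.

    BLOSUM62 entries are half-bit log-odds s_ab = 2*log2(q_ab/(p_a p_b)); the
    implied pair frequencies give row-normalized replacement probabilities used
    by the synthetic mutation model. The diagonal is zeroed so a draw always
    changes the residue.
    """
    s = blosum62()
    q = BACKGROUND[:, None] * BACKGROUND[None, :] * np.exp2(s / 2.0)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)
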