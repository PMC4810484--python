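"""Amino-acid alphabet, background frequencies and substitution scores.

The 20 canonical residues are indexed in the fixed order of :data:`AMINO_ACIDS`;
the ambiguity letter ``X`` is carried as index 20 and scores 0 against
everything.  Background frequencies are the Robinson & Robinson composition
conventionally paired with BLOSUM62.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = 20
ALPHABET_SIZE = 20

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_INDEX["X"] = X_INDEX

# Robinson & Robinson (1991) amino-acid frequencies, order as AMINO_ACIDS.
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND /= BACKGROUND.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode a protein string into int8 indices; raises on illegal residues."""
    try:
        return np.array([_INDEX[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from None


def decode(indices: np.ndarray) -> str:
    return "".join((AMINO_ACIDS + "X")[i] for i in indices)


def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 int matrix in AMINO_ACIDS order; X scores 0."""
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = int(raw[a][b])
    return mat
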