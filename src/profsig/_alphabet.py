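"""Amino-acid alphabet and background composition shared across the package."""

from __future__ import annotations

import numpy as np

#: Canonical residue order used throughout (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = 20

GAP = "-"

# Robinson & Robinson amino-acid background frequencies, reordered to
# AMINO_ACIDS and renormalized.
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

BACKGROUND = np.array([_ROBINSON[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

#: Secondary-structure states (helix, strand, coil).
SS_STATES = "HEC"
N_SS = 3
SS_BACKGROUND = np.full(3, 1.0 / 3.0)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned residue string to integer codes.

    Codes 0..19 are amino acids in :data:`AMINO_ACIDS` order, 20 is the gap
    and 21 is the ambiguity symbol 'X'.
    """
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        c = ch.upper()
        if c in AA_INDEX:
            out[i] = AA_INDEX[c]
        elif c == GAP or c == ".":
            out[i] = 20
        elif c == "X":
            out[i] = 21
        else:
            raise ValueError(f"unsupported residue symbol {ch!r}")
    return out
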