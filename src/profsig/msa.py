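"""Multiple sequence alignments: parsing, sequence weights and the effective
number of observations (ENO).

The ENO of an alignment is the median over columns of the per-column
effective residue count.  The per-column count is computed as the
exponential of the Shannon entropy of the position's weighted residue
composition (sequence weights are position-based Henikoff weights,
renormalized over the rows that are not gapped at that position).  This is a
weighted count of effectively distinct residues: a column of identical
residues counts 1 regardless of alignment depth, and duplicated rows do not
change it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from ._alphabet import BACKGROUND, N_AA, encode_sequence
from .errors import FormatError, InputError

__all__ = ["Msa", "read_msa", "henikoff_weights", "compute_eno"]

_GAP_CODE = 20
_X_CODE = 21


@dataclass
class Msa:
    """A rectangular multiple sequence alignment over the 20-letter amino
    acid alphabet plus gap '-' (and the ambiguity symbol 'X')."""

    sequences: list[str]
    identifiers: list[str]
    weights: np.ndarray | None = None
    #: optional per-column secondary-structure state probabilities (L, 3),
    #: e.g. inherited from the profile model an MSA was sampled from
    ss_probs: np.ndarray | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InputError("alignment must contain at least one sequence")
        width = len(self.sequences[0])
        if width < 1:
            raise InputError("alignment rows must have length >= 1")
        for ident, seq in zip(self.identifiers, self.sequences):
            if len(seq) != width:
                raise FormatError(
                    f"ragged alignment: row {ident!r} has length {len(seq)}, "
                    f"expected {width}"
                )
        if len(self.identifiers) != len(self.sequences):
            raise InputError("one identifier required per sequence")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.sequences):
                raise InputError("one weight required per sequence")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise InputError("weights must be nonnegative with positive sum")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, length)."""
        if self._codes is None:
            try:
                self._codes = np.stack(
                    [encode_sequence(s) for s in self.sequences]
                )
            except ValueError as exc:
                raise InputError(str(exc)) from exc
        return self._codes

    @classmethod
    def from_codes(cls, codes: np.ndarray, identifiers: list[str] | None = None) -> "Msa":
        from ._alphabet import AMINO_ACIDS

        table = AMINO_ACIDS + "-X"
        seqs = ["".join(table[c] for c in row) for row in codes]
        if identifiers is None:
            identifiers = [f"seq{i}" for i in range(len(seqs))]
        msa = cls(seqs, identifiers)
        msa._codes = np.asarray(codes, dtype=np.int8)
        return msa


def read_msa(path, format: str = "afasta") -> Msa:
    """Read an aligned FASTA ('afasta') or A3M ('a3m') file.

    In A3M, lowercase letters denote insert states relative to the match
    columns; they are removed so that all rows project onto the match
    columns.
    """
    if format not in ("afasta", "a3m"):
        raise InputError(f"unknown MSA format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no sequences found in {path}")
    identifiers = [r.id for r in records]
    sequences = []
    for r in records:
        seq = str(r.seq)
        if format == "a3m":
            seq = "".join(ch for ch in seq if not (ch.islower() or ch == "."))
        sequences.append(seq)
    width = len(sequences[0])
    for ident, seq in zip(identifiers, sequences):
        if len(seq) != width:
            raise FormatError(
                f"ragged alignment in {path}: row {ident!r} has length "
                f"{len(seq)}, expected {width}"
            )
        for ch in seq:
            c = ch.upper()
            if c not in "ACDEFGHIKLMNPQRSTVWYX-":
                raise InputError(
                    f"non-amino-acid symbol {ch!r} in row {ident!r}"
                )
    return Msa(sequences, identifiers)


def henikoff_weights(msa: Msa) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), normalized to
    sum to one.  Gap positions contribute nothing; 'X' is treated as its own
    residue type for weighting purposes."""
    codes = msa.codes()
    n, L = codes.shape
    if n == 1:
        return np.ones(1)
    # counts[c, a]: number of rows with code a at column c
    counts = (codes[:, :, None] == np.arange(22)[None, None, :]).sum(axis=0)
    counts_res = counts[:, :_GAP_CODE].astype(float)
    counts_x = counts[:, _X_CODE].astype(float)
    # distinct residue types per column (gap excluded)
    r = (counts_res > 0).sum(axis=1) + (counts_x > 0)
    # per-row contribution 1/(r_c * n_{c, a_i}) over non-gap columns
    n_at = np.empty((n, L))
    for a in range(22):
        mask = codes == a
        if a == _GAP_CODE:
            n_at[mask] = np.inf  # gaps contribute 0
        else:
            col_counts = counts[:, a]
            n_at[mask] = np.broadcast_to(col_counts, (n, L))[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = 1.0 / (r[None, :] * n_at)
    contrib[~np.isfinite(contrib)] = 0.0
    w = contrib.sum(axis=1)
    total = w.sum()
    if total <= 0:
        raise InputError("alignment contains only gaps")
    return w / total


def weighted_composition(codes: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column weighted residue composition (unnormalized) and its total
    mass.  'X' mass is spread according to the background composition; gaps
    carry no mass.  Shapes: (L, 20) and (L,)."""
    n, L = codes.shape
    comp = np.zeros((L, N_AA))
    flat_cols = np.tile(np.arange(L), n)
    flat_codes = codes.ravel()
    flat_w = np.repeat(weights, L)
    res_mask = flat_codes < N_AA
    np.add.at(comp, (flat_cols[res_mask], flat_codes[res_mask]), flat_w[res_mask])
    x_mask = flat_codes == _X_CODE
    if np.any(x_mask):
        x_w = np.zeros(L)
        np.add.at(x_w, flat_cols[x_mask], flat_w[x_mask])
        comp += x_w[:, None] * BACKGROUND[None, :]
    return comp, comp.sum(axis=1)


def _column_effective_counts(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-column effective residue count: exp(entropy) of the weighted
    residue composition over non-gap rows.  All-gap columns yield 0."""
    comp, mass = weighted_composition(codes, weights)
    L = comp.shape[0]
    counts = np.zeros(L)
    ok = mass > 0
    p = comp[ok] / mass[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    counts[ok] = np.exp(-plogp.sum(axis=1))
    return counts


def compute_eno(msa: Msa, weights: np.ndarray | None = None) -> float:
    """Effective number of observations: the median over columns of the
    per-column effective residue count.

    Raises :class:`InputError` if every column is all-gap.
    """
    codes = msa.codes()
    if weights is None:
        weights = msa.weights if msa.weights is not None else henikoff_weights(msa)
    weights = np.asarray(weights, dtype=float)
    counts = _column_effective_counts(codes, weights)
    if np.all(counts == 0):
        raise InputError("all columns are gaps; ENO undefined")
    return float(np.median(counts))
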