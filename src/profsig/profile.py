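"""Profile data model, construction from MSAs, and text-format I/O.

A profile describes a protein family position by position: target amino
acid probabilities, log-odds scores against a background composition,
match/insert/delete transition probabilities (which become position-specific
gap penalties at alignment time), optional secondary-structure state
probabilities, and an effective observation count per position.  Two scalar
attributes summarize the whole profile: its length l and its effective
number of observations (ENO) n.

Profile construction from an MSA uses position-based Henikoff sequence
weights and substitution-matrix pseudocounts derived from BLOSUM62 target
frequencies.  The builder is deliberately plain; any profile source that
produces the same fields can be substituted.

Text format (one file per profile)::

    # comment lines allowed anywhere
    PROFSIG 1
    ID <identifier>
    LEN <ncols>
    ENO <float>
    HAS_SS <0|1>
    BG <20 floats>
    COL <20 target> <20 log-odds> <7 transitions> [<3 ss>] <effcount>
    ... one COL line per position ...
    END

Transition order: M->M, M->I, M->D, I->I, I->M, D->D, D->M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import BACKGROUND, N_AA
from .errors import FormatError, InputError
from .msa import Msa, _column_effective_counts, compute_eno, henikoff_weights, weighted_composition

__all__ = [
    "ProfileColumn",
    "Profile",
    "build_profile_from_msa",
    "write_profile",
    "read_profile",
]

#: transition index order
TRANS_NAMES = ("MM", "MI", "MD", "II", "IM", "DD", "DM")

# default transition prior (typical values for protein families)
_TRANS_PRIOR = np.array([0.92, 0.04, 0.04, 0.40, 0.60, 0.40, 0.60])


@dataclass
class ProfileColumn:
    """A single profile position (views into the parent profile's arrays)."""

    target_probs: np.ndarray
    log_odds: np.ndarray
    trans_probs: np.ndarray
    eff_count: float
    ss_probs: np.ndarray | None = None

    def validate(self) -> None:
        if abs(self.target_probs.sum() - 1.0) > 1e-9 or np.any(self.target_probs < 0):
            raise InputError("target probabilities must be nonnegative and sum to 1")
        if self.ss_probs is not None and abs(self.ss_probs.sum() - 1.0) > 1e-9:
            raise InputError("SS probabilities must sum to 1")
        mm = self.trans_probs[0:3].sum()
        ii = self.trans_probs[3:5].sum()
        dd = self.trans_probs[5:7].sum()
        for s, name in ((mm, "M"), (ii, "I"), (dd, "D")):
            if abs(s - 1.0) > 1e-6:
                raise InputError(f"outgoing transitions from state {name} must sum to 1")


@dataclass
class Profile:
    """A profile of length l with effective number of observations ``eno``."""

    id: str
    target_probs: np.ndarray  # (l, 20)
    log_odds: np.ndarray      # (l, 20)
    trans_probs: np.ndarray   # (l, 7)
    eff_counts: np.ndarray    # (l,)
    eno: float
    background_probs: np.ndarray = None  # (20,)
    ss_probs: np.ndarray | None = None   # (l, 3) or None

    def __post_init__(self) -> None:
        if self.background_probs is None:
            self.background_probs = BACKGROUND.copy()
        self.target_probs = np.asarray(self.target_probs, dtype=float)
        if self.target_probs.ndim != 2 or self.target_probs.shape[1] != N_AA:
            raise InputError("target_probs must have shape (l, 20)")
        if self.length < 1:
            raise InputError("profile must have at least one column")
        if self.eno < 1.0 - 1e-9:
            raise InputError("ENO must be >= 1")

    @property
    def length(self) -> int:
        return self.target_probs.shape[0]

    def column(self, i: int) -> ProfileColumn:
        return ProfileColumn(
            target_probs=self.target_probs[i],
            log_odds=self.log_odds[i],
            trans_probs=self.trans_probs[i],
            eff_count=float(self.eff_counts[i]),
            ss_probs=None if self.ss_probs is None else self.ss_probs[i],
        )

    def validate(self) -> None:
        for i in range(self.length):
            self.column(i).validate()
        if abs(self.background_probs.sum() - 1.0) > 1e-9:
            raise InputError("background probabilities must sum to 1")

    def allclose(self, other: "Profile", atol: float = 1e-6) -> bool:
        if self.length != other.length or (self.ss_probs is None) != (other.ss_probs is None):
            return False
        checks = [
            np.allclose(self.target_probs, other.target_probs, atol=atol),
            np.allclose(self.log_odds, other.log_odds, atol=atol),
            np.allclose(self.trans_probs, other.trans_probs, atol=atol),
            np.allclose(self.eff_counts, other.eff_counts, atol=atol),
            abs(self.eno - other.eno) <= atol,
            np.allclose(self.background_probs, other.background_probs, atol=atol),
        ]
        if self.ss_probs is not None:
            checks.append(np.allclose(self.ss_probs, other.ss_probs, atol=atol))
        return all(checks)


_BLOSUM_COND = None


def _blosum_conditional() -> np.ndarray:
    """C[a, b] = q(a | b): probability of residue a in a BLOSUM62-matched
    pair given residue b, derived from the half-bit log-odds matrix and the
    package background."""
    global _BLOSUM_COND
    if _BLOSUM_COND is None:
        from Bio.Align import substitution_matrices

        from ._alphabet import AMINO_ACIDS

        mat = substitution_matrices.load("BLOSUM62")
        idx = [mat.alphabet.index(a) for a in AMINO_ACIDS]
        scores = np.array(mat)[np.ix_(idx, idx)]
        joint = BACKGROUND[:, None] * BACKGROUND[None, :] * np.power(2.0, scores / 2.0)
        joint /= joint.sum()
        cond = joint / joint.sum(axis=0, keepdims=True)  # columns sum to 1
        _BLOSUM_COND = cond
    return _BLOSUM_COND


def _estimate_transitions(codes: np.ndarray, weights: np.ndarray,
                          prior_strength: float) -> np.ndarray:
    """Weighted transition counts between consecutive match columns with a
    Dirichlet prior.  Gaps are delete states; insert states are unobserved
    after projection onto match columns and keep their prior."""
    n, L = codes.shape
    is_res = codes < 20  # X counts as residue
    trans = np.empty((L, 7))
    prior = _TRANS_PRIOR * prior_strength
    w = weights
    for i in range(L):
        j = min(i + 1, L - 1)
        m_now = is_res[:, i]
        m_next = is_res[:, j]
        if i == L - 1:
            # terminal column: prior only
            mm, mi, md = prior[0], prior[1], prior[2]
            dd, dm = prior[5], prior[6]
        else:
            mm = prior[0] + w[m_now & m_next].sum()
            mi = prior[1]
            md = prior[2] + w[m_now & ~m_next].sum()
            dd = prior[5] + w[~m_now & ~m_next].sum()
            dm = prior[6] + w[~m_now & m_next].sum()
        ii, im = prior[3], prior[4]
        trans[i, 0:3] = np.array([mm, mi, md]) / (mm + mi + md)
        trans[i, 3:5] = np.array([ii, im]) / (ii + im)
        trans[i, 5:7] = np.array([dd, dm]) / (dd + dm)
    return trans


def build_profile_from_msa(
    msa: Msa,
    pseudocount_strength: float = 2.0,
    background: np.ndarray | None = None,
    id: str | None = None,
    ss_probs: np.ndarray | None = None,
    trans_prior_strength: float = 3.0,
) -> Profile:
    """Build a profile from an MSA.

    Per-column target probabilities are the Henikoff-weighted residue
    frequencies mixed with substitution-matrix pseudocounts:
    ``t = (m*f + tau*g) / (m + tau)`` where m is the column's effective
    count, f the weighted frequencies, g the BLOSUM62-conditional
    pseudocount distribution and tau the pseudocount strength.
    """
    if pseudocount_strength < 0:
        raise InputError("pseudocount_strength must be >= 0")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise InputError("background probabilities must be strictly positive")
    codes = msa.codes()
    weights = msa.weights if msa.weights is not None else henikoff_weights(msa)
    comp, mass = weighted_composition(codes, weights)
    eff = _column_effective_counts(codes, weights)
    L = codes.shape[1]
    freqs = np.where(mass[:, None] > 0, comp / np.maximum(mass, 1e-300)[:, None],
                     bg[None, :])
    cond = _blosum_conditional()
    pseudo = freqs @ cond.T  # g_a = sum_b f_b q(a|b)
    m = np.maximum(eff, 1e-6)[:, None]
    tau = pseudocount_strength
    target = (m * freqs + tau * pseudo) / (m + tau)
    target /= target.sum(axis=1, keepdims=True)
    log_odds = np.log(target / bg[None, :])
    trans = _estimate_transitions(codes, weights, trans_prior_strength)
    eno = compute_eno(msa, weights)
    return Profile(
        id=id or (msa.identifiers[0] if msa.identifiers else "profile"),
        target_probs=target,
        log_odds=log_odds,
        trans_probs=trans,
        eff_counts=np.maximum(eff, 1.0),
        eno=max(eno, 1.0),
        background_probs=bg,
        ss_probs=ss_probs,
    )


def write_profile(profile: Profile, path) -> None:
    """Write a profile in the package text format (see module docstring)."""
    has_ss = profile.ss_probs is not None
    with open(path, "w") as fh:
        fh.write("PROFSIG 1\n")
        fh.write(f"ID {profile.id}\n")
        fh.write(f"LEN {profile.length}\n")
        fh.write(f"ENO {profile.eno:.9g}\n")
        fh.write(f"HAS_SS {int(has_ss)}\n")
        fh.write("BG " + " ".join(f"{v:.9g}" for v in profile.background_probs) + "\n")
        for i in range(profile.length):
            parts = (
                list(profile.target_probs[i])
                + list(profile.log_odds[i])
                + list(profile.trans_probs[i])
                + (list(profile.ss_probs[i]) if has_ss else [])
                + [profile.eff_counts[i]]
            )
            fh.write("COL " + " ".join(f"{v:.9g}" for v in parts) + "\n")
        fh.write("END\n")


def read_profile(path) -> Profile:
    """Read a profile written by :func:`write_profile`."""
    header: dict[str, str] = {}
    cols: list[list[float]] = []
    saw_end = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "COL":
                try:
                    cols.append([float(t) for t in tokens[1:]])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad COL line") from exc
            elif tag == "END":
                saw_end = True
                break
            else:
                header[tag] = " ".join(tokens[1:])
    if not saw_end:
        raise FormatError(f"{path}: truncated file (missing END)")
    for key in ("PROFSIG", "ID", "LEN", "ENO", "HAS_SS", "BG"):
        if key not in header:
            raise FormatError(f"{path}: missing header line {key}")
    length = int(header["LEN"])
    has_ss = bool(int(header["HAS_SS"]))
    if len(cols) != length:
        raise FormatError(
            f"{path}: header declares {length} columns but {len(cols)} COL "
            "lines found"
        )
    ncol = 20 + 20 + 7 + (3 if has_ss else 0) + 1
    for i, c in enumerate(cols):
        if len(c) != ncol:
            raise FormatError(f"{path}: COL line {i + 1} has {len(c)} fields, expected {ncol}")
    arr = np.asarray(cols, dtype=float)
    bg = np.asarray([float(t) for t in header["BG"].split()], dtype=float)
    ss = arr[:, 47:50] if has_ss else None
    return Profile(
        id=header["ID"],
        target_probs=arr[:, 0:20],
        log_odds=arr[:, 20:40],
        trans_probs=arr[:, 40:47],
        eff_counts=arr[:, -1],
        eno=float(header["ENO"]),
        background_probs=bg,
        ss_probs=ss,
    )
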