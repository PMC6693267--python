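"""Profile-profile scoring and local alignment.

The reference substitution score for two profile columns is the symmetric
log-odds score

    score(c1, c2) = 1/2 * sum_a f1(a) log(f2(a)/b(a))
                  + 1/2 * sum_a f2(a) log(f1(a)/b(a)),

optionally augmented by a secondary-structure log-odds term
``ss_weight * log( sum_t p1ss(t) p2ss(t) / sum_t bss(t)^2 )`` when both
columns carry SS state probabilities (bss uniform over H/E/C).  Any scorer
whose per-pair expectation is negative with some positive probability mass
can be plugged in; the significance machinery downstream does not depend on
this particular functional form.

Gap penalties are position specific: each profile converts its
match->insert/delete transition probabilities into per-position open and
extension costs, and at alignment time the costs of the two profiles are
averaged.  Local alignment is standard Smith-Waterman with affine
(positional) gaps; ties during traceback prefer diagonal over vertical over
horizontal moves, and the terminus is the highest-scoring cell with the
smallest (i, j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._alphabet import BACKGROUND, SS_BACKGROUND
from .errors import InputError
from .profile import Profile, ProfileColumn

logger = logging.getLogger(__name__)

__all__ = [
    "ScorerConfig",
    "ScoreMatrix",
    "GapModel",
    "AlignmentResult",
    "substitution_score",
    "build_score_matrix",
    "gap_costs_from_transitions",
    "local_align",
]


@dataclass
class ScorerConfig:
    """Configuration of the column-pair scorer and gap model.

    ``score_scale`` sets the score units: the raw symmetric log-odds score
    (natural-log units) is multiplied by this factor before alignment.  The
    default of 10 (deci-nat units) places typical compositional-similarity
    values lambda_u of unrelated profile pairs in the range resolved by the
    0.1-wide calibration bins.  Gap costs are expressed in the same units.
    """

    ss_weight: float = 0.5
    score_scale: float = 10.0
    gap_scale: float = 6.0
    min_gap_cost: float = 2.0
    max_gap_cost: float = 60.0

    def __post_init__(self) -> None:
        if self.ss_weight < 0:
            raise InputError("ss_weight must be >= 0")
        if self.gap_scale <= 0 or self.score_scale <= 0:
            raise InputError("gap_scale and score_scale must be > 0")


@dataclass
class ScoreMatrix:
    values: np.ndarray  # (l1, l2)

    @property
    def l1(self) -> int:
        return self.values.shape[0]

    @property
    def l2(self) -> int:
        return self.values.shape[1]


@dataclass
class GapModel:
    """Per-position gap costs (mode 'positional') or scalars broadcast to
    every position (mode 'affine')."""

    mode: str
    open_cost: np.ndarray  # (l,)
    extend_cost: np.ndarray  # (l,)

    def __post_init__(self) -> None:
        self.open_cost = np.atleast_1d(np.asarray(self.open_cost, dtype=float))
        self.extend_cost = np.atleast_1d(np.asarray(self.extend_cost, dtype=float))
        if np.any(self.open_cost < 0) or np.any(self.extend_cost < 0):
            raise InputError("gap costs must be nonnegative")
        if np.any(self.extend_cost > self.open_cost + 1e-12):
            raise InputError("extend_cost must not exceed open_cost")

    @classmethod
    def affine(cls, open_cost: float, extend_cost: float) -> "GapModel":
        return cls("affine", np.array([open_cost]), np.array([extend_cost]))

    def per_position(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        if self.mode == "affine" or len(self.open_cost) == 1:
            return (np.full(length, self.open_cost[0]),
                    np.full(length, self.extend_cost[0]))
        if len(self.open_cost) != length:
            raise InputError("positional gap model length mismatch")
        return self.open_cost, self.extend_cost


@dataclass
class AlignmentResult:
    """A local alignment: score x, path, and the count omega of aligned
    column pairs with positive substitution score."""

    score: float
    path: list[tuple[int, int]]  # (-1, j) / (i, -1) encode gap steps
    omega: int
    l1: int
    l2: int
    lambda_u: float | None = field(default=None)

    @property
    def n_aligned_pairs(self) -> int:
        return sum(1 for i, j in self.path if i >= 0 and j >= 0)


def substitution_score(
    col1: ProfileColumn,
    col2: ProfileColumn,
    background: np.ndarray | None = None,
    ss_weight: float = 0.0,
) -> float:
    """Symmetric log-odds score of two profile columns (natural-log units)."""
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise InputError("background probabilities must be strictly positive")
    f1, f2 = col1.target_probs, col2.target_probs
    s = 0.5 * float(f1 @ np.log(f2 / bg) + f2 @ np.log(f1 / bg))
    if ss_weight > 0 and col1.ss_probs is not None and col2.ss_probs is not None:
        s += ss_weight * float(
            np.log((col1.ss_probs @ col2.ss_probs) / (SS_BACKGROUND @ SS_BACKGROUND))
        )
    return s


def build_score_matrix(p1: Profile, p2: Profile, config: ScorerConfig | None = None) -> ScoreMatrix:
    """All-against-all column scores between two profiles (vectorized)."""
    config = config or ScorerConfig()
    bg = p1.background_probs
    lo1 = np.log(p1.target_probs / bg[None, :])
    lo2 = np.log(p2.target_probs / bg[None, :])
    values = 0.5 * (p1.target_probs @ lo2.T + lo1 @ p2.target_probs.T)
    if config.ss_weight > 0 and p1.ss_probs is not None and p2.ss_probs is not None:
        dot = p1.ss_probs @ p2.ss_probs.T
        values = values + config.ss_weight * (np.log(dot) - np.log(SS_BACKGROUND @ SS_BACKGROUND))
    return ScoreMatrix(np.ascontiguousarray(config.score_scale * values))


def gap_costs_from_transitions(profile: Profile, scale: float,
                               min_cost: float = 0.2, max_cost: float = 8.0) -> GapModel:
    """Positional gap costs from a profile's transition probabilities.

    open(i)  = -scale * log(P_i(M->I) + P_i(M->D))
    extend(i) = -scale * log(mean(P_i(I->I), P_i(D->D)))

    Costs are clipped to [min_cost, max_cost]; vanishing transition
    probabilities therefore yield the maximum cost rather than infinity.
    """
    if scale <= 0:
        raise InputError("scale must be > 0")
    tr = profile.trans_probs
    p_open = tr[:, 1] + tr[:, 2]
    p_ext = 0.5 * (tr[:, 3] + tr[:, 5])
    if np.any(p_open <= 0) or np.any(p_ext <= 0):
        logger.warning("zero transition probability; gap cost clipped at bound")
    with np.errstate(divide="ignore"):
        open_cost = np.clip(-scale * np.log(np.maximum(p_open, 1e-300)), min_cost, max_cost)
        extend_cost = np.clip(-scale * np.log(np.maximum(p_ext, 1e-300)), min_cost, max_cost)
    extend_cost = np.minimum(extend_cost, open_cost)
    return GapModel("positional", open_cost, extend_cost)


@njit(cache=True)
def _sw_kernel(S, open1, ext1, open2, ext2):  # pragma: no cover - numba
    l1, l2 = S.shape
    H = np.zeros((l1 + 1, l2 + 1))
    E = np.zeros((l1 + 1, l2 + 1))  # gap in profile 1 (consumes j)
    F = np.zeros((l1 + 1, l2 + 1))  # gap in profile 2 (consumes i)
    ptrH = np.zeros((l1 + 1, l2 + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 F, 3 E
    ptrE = np.zeros((l1 + 1, l2 + 1), dtype=np.int8)  # 1: from H, 0: extend
    ptrF = np.zeros((l1 + 1, l2 + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, l1 + 1):
        for j in range(1, l2 + 1):
            go = 0.5 * (open1[i - 1] + open2[j - 1])
            ge = 0.5 * (ext1[i - 1] + ext2[j - 1])
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            # tie preference: diagonal > vertical (F) > horizontal (E)
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    max_steps = l1 + l2 + 1
    path_i = np.empty(max_steps, dtype=np.int64)
    path_j = np.empty(max_steps, dtype=np.int64)
    nsteps = 0
    i, j = bi, bj
    state = 0  # 0: in H, 2: in F, 3: in E
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                path_i[nsteps] = i - 1
                path_j[nsteps] = j - 1
                nsteps += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:  # F: gap in profile 2, consumes i
            path_i[nsteps] = i - 1
            path_j[nsteps] = -1
            nsteps += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
        else:  # E: gap in profile 1, consumes j
            path_i[nsteps] = -1
            path_j[nsteps] = j - 1
            nsteps += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
    return best, path_i[:nsteps], path_j[:nsteps]


def local_align(
    p1: Profile,
    p2: Profile,
    config: ScorerConfig | None = None,
    gaps: tuple[GapModel, GapModel] | GapModel | None = None,
    matrix: ScoreMatrix | None = None,
    check_expectation: bool = True,
) -> AlignmentResult:
    """Optimal local alignment of two profiles.

    Returns the alignment score x, the traceback path (pairs with -1
    marking gap steps, ordered from alignment start), and omega, the number
    of aligned pairs whose substitution score is positive.
    """
    if p1.length < 1 or p2.length < 1:
        raise InputError("profiles must be nonempty")
    config = config or ScorerConfig()
    if matrix is None:
        matrix = build_score_matrix(p1, p2, config)
    S = matrix.values
    if check_expectation and (S.mean() >= 0 or S.max() <= 0):
        logger.warning(
            "score matrix violates local-alignment conditions "
            "(mean %.3f, max %.3f)", S.mean(), S.max()
        )
    if gaps is None:
        g1 = gap_costs_from_transitions(p1, config.gap_scale, config.min_gap_cost, config.max_gap_cost)
        g2 = gap_costs_from_transitions(p2, config.gap_scale, config.min_gap_cost, config.max_gap_cost)
    elif isinstance(gaps, GapModel):
        g1 = g2 = gaps
    else:
        g1, g2 = gaps
    o1, e1 = g1.per_position(p1.length)
    o2, e2 = g2.per_position(p2.length)
    score, path_i, path_j = _sw_kernel(
        np.ascontiguousarray(S, dtype=np.float64),
        np.ascontiguousarray(o1, dtype=np.float64),
        np.ascontiguousarray(e1, dtype=np.float64),
        np.ascontiguousarray(o2, dtype=np.float64),
        np.ascontiguousarray(e2, dtype=np.float64),
    )
    path = [(int(a), int(b)) for a, b in zip(path_i[::-1], path_j[::-1])]
    omega = int(sum(1 for i, j in path if i >= 0 and j >= 0 and S[i, j] > 0))
    return AlignmentResult(score=float(score), path=path, omega=omega,
                           l1=p1.length, l2=p2.length)
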