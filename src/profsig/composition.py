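"""Compositional similarity between two profiles.

The statistical parameter lambda_u is the unique positive root of

    sum_k p(s_k) exp(lambda_u * s_k) = 1,

where {s_k} are the distinct values of the pairwise substitution-score
matrix of the two profiles and p(s_k) their probabilities (each of the
l1*l2 cells weighted equally).  lambda_u decreases as probability mass
moves onto positive scores, so low values indicate high compositional
similarity between the profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .alignment import ScoreMatrix
from .errors import ConditionError, InputError

__all__ = [
    "PairScoreDistribution",
    "score_distribution",
    "solve_lambda_u",
    "discretize_lambda_u",
]


@dataclass
class PairScoreDistribution:
    """Discrete distribution of pairwise substitution scores."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape or self.support.size == 0:
            raise InputError("support and probs must be nonempty and congruent")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise InputError("probabilities must be nonnegative and sum to 1")
        order = np.argsort(self.support)
        self.support = self.support[order]
        self.probs = self.probs[order]

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)


def score_distribution(matrix: ScoreMatrix | np.ndarray, bin_width: float = 0.05) -> PairScoreDistribution:
    """Bin all matrix entries to multiples of ``bin_width`` with equal weight
    per cell."""
    if bin_width <= 0:
        raise InputError("bin_width must be > 0")
    values = matrix.values if isinstance(matrix, ScoreMatrix) else np.asarray(matrix)
    if values.size == 0:
        raise InputError("empty score matrix")
    k = np.rint(values.ravel() / bin_width).astype(np.int64)
    kmin = k.min()
    counts = np.bincount(k - kmin)
    nz = np.nonzero(counts)[0]
    support = (nz + kmin) * bin_width
    probs = counts[nz] / values.size
    return PairScoreDistribution(support, probs)


def solve_lambda_u(dist: PairScoreDistribution, tol: float = 1e-12) -> float:
    """Positive root of ``sum p(s_k) exp(lambda s_k) = 1``.

    The left side minus one is convex with negative slope at zero (the mean
    score must be negative) and diverges whenever some positive score has
    positive mass, so a unique positive root exists; it is located by
    geometric bracket expansion followed by Brent's method.
    """
    s, p = dist.support, dist.probs
    if dist.mean >= 0:
        raise ConditionError("no positive root: expected score is nonnegative")
    if s[-1] <= 0 or p[s > 0].sum() <= 0:
        raise ConditionError("no positive root: no positive score with mass")

    def g(lam: float) -> float:
        # stabilized: factor out the largest exponent
        z = lam * s
        zmax = z.max()
        return math.exp(zmax) * float(p @ np.exp(z - zmax)) - 1.0

    # g(0) = 0 is the trivial root; start strictly inside the negative dip
    lo = 1e-8
    while g(lo) >= 0 and lo > 1e-300:
        lo /= 16.0
    hi = max(1.0, 2 * lo)
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ConditionError("failed to bracket the positive root")
    root = brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(root)


def discretize_lambda_u(lambda_u: float, bin_width: float = 0.1) -> float:
    """Round to the nearest multiple of ``bin_width`` (halves round up)."""
    if lambda_u <= 0:
        raise InputError("lambda_u must be > 0")
    # the 1e-9 guards exact halves against binary representation error
    k = math.floor(lambda_u / bin_width + 0.5 + 1e-9)
    return float(np.round(k * bin_width, 6))
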