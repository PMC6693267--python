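"""Per-alignment significance: P_a, omega_n, P_o, combined p-values and
E-values.

The alignment-score p-value P_a comes from the Gumbel upper tail.  The
second statistic, omega, counts positive substitution scores on the
alignment path; because its information content shrinks with the search
space, it is normalized to

    omega_n = round( c0 * omega / (l1*l2)^(3/2) ),   c0 = 1e5,

the nearest-integer statistic whose value matches omega when the search
space is about that of two length-50 profiles ((l1*l2)^(3/2) = 1e5 for
l1 = l2 slightly below 50).  Its null distribution is negative binomial,
giving P_o = P(W >= omega_n) (P_o = 1 at omega_n = 0).

P_a and P_o are dependent, so they are combined with the empirical Brown
method: psi = -2(ln P_a + ln P_o) is compared to a scaled chi-square
c * chi2_f whose c and f are moment-matched to psi over null alignments
(f = 4, c = 1 recovers Fisher's method under independence; f -> 2 under
perfect dependence).

E-values and p-values relate by P = 1 - exp(-E); an E-value computed
against a search space of total length l_N' converts to a database of
total length l_N by E_N = (l_N / l_N') * E_N'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError
from .tailstats import EVDParams, NBDParams

__all__ = [
    "BrownParams",
    "SignificanceReport",
    "C0",
    "pvalue_alignment_score",
    "omega_n_statistic",
    "pvalue_omega",
    "calibrate_brown",
    "combine_brown",
    "evalue_and_correction",
    "significance_report",
]

C0 = 1e5
PVAL_FLOOR = 1e-300
EVALUE_CAP = 1e300


@dataclass
class BrownParams:
    """Moment-matched scaled chi-square for psi = -2(ln P_a + ln P_o)."""

    mean_psi: float
    var_psi: float

    def __post_init__(self) -> None:
        if self.mean_psi <= 0 or self.var_psi <= 0:
            raise InputError("psi moments must be positive")

    @property
    def f(self) -> float:
        """Degrees of freedom, capped at the independence value 4."""
        return min(2.0 * self.mean_psi ** 2 / self.var_psi, 4.0)

    @property
    def c(self) -> float:
        """Scale; c*f always preserves mean_psi."""
        return self.mean_psi / self.f


def pvalue_alignment_score(x, params: EVDParams):
    """Gumbel upper-tail p-value P_a = 1 - exp(-exp(-(x - mu)/sigma)),
    evaluated without underflow far in the tail."""
    z = (np.asarray(x, dtype=float) - params.mu) / params.sigma
    t = np.exp(-z)
    out = -np.expm1(-t)
    if np.ndim(x) == 0:
        return float(out)
    return out


def omega_n_statistic(omega, l1: int, l2: int):
    """Search-space-normalized count of positive substitution scores
    (round-half-to-even to the nearest integer)."""
    if l1 < 1 or l2 < 1:
        raise InputError("profile lengths must be >= 1")
    omega = np.asarray(omega)
    if np.any(omega < 0):
        raise InputError("omega must be >= 0")
    val = C0 * omega / float(l1 * l2) ** 1.5
    out = np.rint(val).astype(int)
    if np.ndim(omega) == 0:
        return int(out)
    return out


def pvalue_omega(omega_n, nbd: NBDParams):
    """P_o = P(W >= omega_n) under the null NBD; 1 when omega_n = 0."""
    out = np.asarray(nbd.sf_geq(omega_n), dtype=float)
    out = np.where(np.asarray(omega_n) <= 0, 1.0, out)
    if np.ndim(omega_n) == 0:
        return float(out)
    return out


def calibrate_brown(null_pairs) -> BrownParams:
    """Empirical Brown calibration from null (P_a, P_o) pairs.

    psi_i = -2(ln P_a,i + ln P_o,i); the scaled-chi-square parameters
    derive from the sample mean and variance of psi.  Zero p-values are
    floored at 1e-300.
    """
    arr = np.asarray(null_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 500:
        raise InputError("need >= 500 null (P_a, P_o) pairs")
    arr = np.maximum(arr, PVAL_FLOOR)
    psi = -2.0 * (np.log(arr[:, 0]) + np.log(arr[:, 1]))
    return BrownParams(mean_psi=float(psi.mean()),
                       var_psi=float(psi.var(ddof=1)))


def combine_brown(p_a, p_o, brown: BrownParams):
    """Combined p-value P(c * chi2_f >= psi)."""
    p_a = np.maximum(np.asarray(p_a, dtype=float), PVAL_FLOOR)
    p_o = np.maximum(np.asarray(p_o, dtype=float), PVAL_FLOOR)
    psi = -2.0 * (np.log(p_a) + np.log(p_o))
    out = stats.chi2.sf(psi / brown.c, brown.f)
    if np.ndim(p_a) == 0 and np.ndim(p_o) == 0:
        return float(out)
    return out


def evalue_and_correction(P: float, l_n: float, l_nprime: float) -> tuple[float, float]:
    """E-value from a p-value, and its correction across database sizes.

    E_N' = -ln(1 - P) for the search space of total length l_N'; the
    corrected E-value for a database of total length l_N is
    E_N = (l_N / l_N') * E_N'.
    """
    if l_n <= 0 or l_nprime <= 0:
        raise InputError("database sizes must be positive")
    if not (0 <= P <= 1):
        raise InputError("P must lie in [0, 1]")
    if P >= 1:
        return EVALUE_CAP, EVALUE_CAP
    e_nprime = -math.log1p(-P)
    e_n = (l_n / l_nprime) * e_nprime
    return min(e_nprime, EVALUE_CAP), min(e_n, EVALUE_CAP)


@dataclass
class SignificanceReport:
    """Everything reported for one profile-profile alignment."""

    x: float
    omega: int
    omega_n: int
    lambda_u: float
    p_a: float
    p_o: float
    p_combined: float
    evalue: float
    evalue_corrected: float
    p_corrected: float
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_a", "p_o", "p_combined"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InputError(f"{name} outside [0, 1]")
        # consistency of the P = 1 - exp(-E) relation for the pair E-value
        if self.evalue < 1e300:
            recon = -math.expm1(-self.evalue)
            if abs(recon - self.p_combined) > 1e-9:
                raise InputError("E-value inconsistent with combined p-value")


def significance_report(alignment, model, n1: float, n2: float,
                        lambda_u: float,
                        db_size: float | None = None) -> SignificanceReport:
    """Complete significance estimate for one alignment.

    ``alignment`` is an :class:`profsig.alignment.AlignmentResult` carrying
    x, omega and the profile lengths; ``model`` is a calibrated
    :class:`profsig.model.StatModel`; n1, n2 are the two profiles' ENOs and
    ``lambda_u`` the pair's compositional similarity (attributes outside
    the calibrated grid are clamped to its hull).  ``db_size`` is the
    searched database's total profile length; per-pair statistics use the
    subject length l2 as the reference search space, so the corrected
    E-value extrapolates the pair E-value to the database.
    """
    x, omega, l1, l2 = alignment.score, alignment.omega, alignment.l1, alignment.l2
    evd = model.predict_evd(n1=n1, l1=l1, n2=n2, l2=l2, lambda_u=lambda_u)
    p_a = pvalue_alignment_score(x, evd)
    w_n = omega_n_statistic(omega, l1, l2)
    p_o = pvalue_omega(w_n, model.nbd)
    p = combine_brown(p_a, p_o, model.brown)
    if hasattr(model, "calibrate_pvalue"):
        p = float(model.calibrate_pvalue(p))
    e_pair, e_db = evalue_and_correction(p, db_size or l2, l2)
    p_corr = -math.expm1(-e_db)
    return SignificanceReport(
        x=x, omega=int(omega), omega_n=int(w_n), lambda_u=float(lambda_u),
        p_a=float(p_a), p_o=float(p_o), p_combined=float(p),
        evalue=float(e_pair), evalue_corrected=float(e_db),
        p_corrected=float(p_corr),
        params_used={"mu": evd.mu, "sigma": evd.sigma},
    )
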