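"""Right-tail extreme-value fitting and goodness-of-fit statistics.

Local alignment scores of unrelated profiles follow a Gumbel (type-1
extreme value) law.  The fit is performed on the right tail: scores above
the empirical (1 - tail_fraction) quantile enter the likelihood through the
Gumbel density, while the remaining mass is left-censored at the threshold.
Goodness of fit in the upper tail is measured by the supremum-class
upper-tail Anderson-Darling statistic

    AD_up = sqrt(N) * sup_{x >= t} (Fhat(x) - F(x)) / (1 - F(x)),

normalized as AD*_up = AD_up / sqrt(N) to remove the sample-size
dependence.  Because the EVD parameters are estimated from the same data,
critical values come from a parametric bootstrap rather than fixed tables.

The number of positive substitution scores per alignment (and its
search-space-normalized variant) is modelled by a negative binomial
distribution fitted by maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InputError

__all__ = [
    "EVDParams",
    "NBDParams",
    "fit_evd_tail",
    "ad_up_statistic",
    "ad_up_test",
    "ks_two_sample",
    "fit_nbd",
]

EULER_GAMMA = 0.5772156649015329


@dataclass
class EVDParams:
    """Gumbel location/scale on the full-distribution scale."""

    mu: float
    sigma: float
    n_scores: int = 0
    tail_threshold: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InputError("sigma must be > 0")

    @property
    def lam(self) -> float:
        """Karlin-Altschul lambda = 1/sigma."""
        return 1.0 / self.sigma

    def K(self, m: float, n: float) -> float:
        """Karlin-Altschul K for search space m*n: K = exp(lambda*mu)/(m*n)."""
        if m <= 0 or n <= 0:
            raise InputError("search-space dimensions must be positive")
        return math.exp(self.lam * self.mu) / (m * n)

    def cdf(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return np.exp(-np.exp(-z))

    def sf(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return -np.expm1(-np.exp(-z))


@dataclass
class NBDParams:
    """Negative binomial with dispersion ``size`` and success probability
    ``p_success``; mean = size*(1-p)/p."""

    size: float
    p_success: float
    poisson_fallback: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0 or not (0 < self.p_success < 1):
            raise InputError("invalid NBD parameters")

    @property
    def mean(self) -> float:
        return self.size * (1 - self.p_success) / self.p_success

    def sf_geq(self, k) -> np.ndarray:
        """P(W >= k); equals 1 for k <= 0."""
        k = np.asarray(k)
        return stats.nbinom.sf(k - 1, self.size, self.p_success)


def _gumbel_censored_nll(params: np.ndarray, tail: np.ndarray, n_below: int,
                         threshold: float) -> float:
    mu, log_sigma = params
    sigma = math.exp(log_sigma)
    z = (tail - mu) / sigma
    nll = tail.size * log_sigma + float(np.sum(z + np.exp(-z)))
    if n_below > 0:
        zt = (threshold - mu) / sigma
        # log F(t) = -exp(-zt)
        nll += n_below * math.exp(-zt)
    return nll


def fit_evd_tail(scores, tail_fraction: float = 0.10) -> EVDParams:
    """Censored maximum-likelihood Gumbel fit to the right tail.

    Scores above the empirical (1 - tail_fraction) quantile contribute
    density terms; the rest contribute the censoring mass F(threshold).
    With ``tail_fraction=1`` this is the ordinary full-sample Gumbel MLE.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    if x.size < 100:
        raise InputError("need at least 100 scores for a tail fit")
    if not (0 < tail_fraction <= 1):
        raise InputError("tail_fraction must be in (0, 1]")
    if x[-1] - x[0] <= 0:
        raise FitError("degenerate sample: all scores equal")
    sd = float(np.std(x))
    sigma0 = max(sd * math.sqrt(6) / math.pi, 1e-6)
    mu0 = float(np.mean(x)) - EULER_GAMMA * sigma0
    if tail_fraction >= 1:
        threshold = -np.inf
        tail = x
        n_below = 0
    else:
        threshold = float(np.quantile(x, 1 - tail_fraction))
        tail = x[x > threshold]
        n_below = x.size - tail.size
        if tail.size < 10:
            raise FitError("tail too small for fitting")
    res = optimize.minimize(
        _gumbel_censored_nll,
        np.array([mu0, math.log(sigma0)]),
        args=(tail, n_below, threshold),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise FitError(f"Gumbel tail fit did not converge: {res.message}")
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return EVDParams(mu=mu, sigma=sigma, n_scores=int(x.size),
                     tail_threshold=None if n_below == 0 else threshold,
                     converged=True)


def ad_up_statistic(scores, params: EVDParams) -> tuple[float, float]:
    """Supremum-class upper-tail Anderson-Darling statistic and its
    normalized form AD*_up = AD_up / sqrt(N).

    The supremum of the tail-weighted ECDF deviation |Fhat - F| / (1 - F)
    is taken over the sample points at or above the fit threshold (the
    whole sample if the fit was uncensored).  The ECDF uses the Hazen
    convention (i - 1/2)/n, which keeps the weighted deviation at the top
    order statistic finite and informative.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = x.size
    if n < 20:
        raise InputError("need at least 20 scores")
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    if params.tail_threshold is not None:
        mask = x >= params.tail_threshold
    else:
        mask = np.ones(n, dtype=bool)
    F = params.cdf(x[mask])
    dev = np.abs(ecdf[mask] - F) / np.maximum(1.0 - F, 1e-300)
    sup = float(dev.max())
    ad_up = math.sqrt(n) * sup
    return ad_up, ad_up / math.sqrt(n)


def ad_up_test(scores, tail_fraction: float = 0.10, alpha: float = 0.05,
               n_boot: int = 200, rng: np.random.Generator | None = None) -> tuple[bool, float]:
    """Parametric-bootstrap goodness-of-fit test of the right-tail EVD fit.

    Simulates samples from the fitted Gumbel law, refits each with the same
    protocol and compares the observed AD*_up to the bootstrap distribution.
    Returns (reject, p_gof).
    """
    if not (0 < alpha <= 1):
        raise InputError("alpha must be in (0, 1]")
    if n_boot < 200:
        raise InputError("n_boot must be >= 200")
    rng = rng or np.random.default_rng()
    x = np.asarray(scores, dtype=float)
    params = fit_evd_tail(x, tail_fraction)
    _, obs = ad_up_statistic(x, params)
    count = 0
    n = x.size
    for _ in range(n_boot):
        sim = rng.gumbel(params.mu, params.sigma, size=n)
        try:
            p_b = fit_evd_tail(sim, tail_fraction)
            _, stat_b = ad_up_statistic(sim, p_b)
        except FitError:
            continue
        if stat_b >= obs:
            count += 1
    p_gof = (1 + count) / (2 + n_boot)
    return p_gof < alpha, p_gof


def ks_two_sample(sample1, sample2) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |F1 - F2|."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be nonempty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def fit_nbd(counts) -> NBDParams:
    """Maximum-likelihood negative binomial fit with method-of-moments
    initialization.  Underdispersed data fall back to a near-Poisson limit
    (very large dispersion) with ``poisson_fallback=True``."""
    k = np.asarray(counts)
    if np.any(k < 0):
        raise InputError("counts must be nonnegative")
    mean = float(k.mean())
    var = float(k.var(ddof=1)) if k.size > 1 else 0.0
    if mean <= 0:
        # all-zero counts: degenerate; report a tiny-mean NBD with warning
        return NBDParams(size=1.0, p_success=1 - 1e-9, poisson_fallback=True)
    if var <= mean:
        size = 1e6
        return NBDParams(size=size, p_success=size / (size + mean),
                         poisson_fallback=True)
    size0 = mean * mean / (var - mean)

    def nll(log_size: float) -> float:
        size = math.exp(log_size)
        p = size / (size + mean)  # profile likelihood: p at its ML value
        return -float(np.sum(stats.nbinom.logpmf(k, size, p)))

    res = optimize.minimize_scalar(
        nll, bracket=(math.log(size0) - 1, math.log(size0) + 1), method="brent",
        options={"xtol": 1e-8},
    )
    size = float(math.exp(res.x))
    return NBDParams(size=size, p_success=size / (size + mean))
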