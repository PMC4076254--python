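"""Beta-binomial distribution and minimum-Kolmogorov-Smirnov fitting.

The beta binomial BB(k | K, alpha, beta) is the tally distribution obtained
when a per-trial success probability p is itself Beta(alpha, beta) distributed
and k ~ Binomial(K, p).  It accommodates the overdispersion produced by
correlated submodels in an ensemble classifier: unlike the binomial it can be
convex (alpha < 1 and beta < 1) as well as concave, and at alpha = beta = 1 it
reduces to the discrete uniform distribution on 0..K.

Fitting here is by minimum Kolmogorov-Smirnov distance between the cumulative
beta binomial and the empirical cumulative distribution of (possibly
continuity-corrected, hence non-integer) tally counts — not maximum
likelihood.  The K-S criterion is robust to the sparsely populated
intermediate tallies that dominate well-performing ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "BetaBinomial",
    "FitResult",
    "bb_pmf",
    "bb_cdf",
    "bb_mean",
    "binomial_pmf",
    "fit_betabinomial",
]

# alpha/beta outside these bounds indicate degenerate counts, not a usable fit
_PARAM_LO = 1e-3
_PARAM_HI = 1e4


@dataclass(frozen=True)
class BetaBinomial:
    """Beta-binomial distribution on tallies 0..K.

    Parameters
    ----------
    K : int
        Number of trials (submodels in the ensemble), >= 1.
    alpha, beta : float
        Positive shape parameters of the mixing Beta distribution.
    """

    K: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.K < 1 or int(self.K) != self.K:
            raise ValueError(f"K must be an integer >= 1, got {self.K}")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"alpha and beta must be positive, got {self.alpha}, {self.beta}"
            )

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.K + 1)

    def pmf(self, k) -> np.ndarray | float:
        return bb_pmf(k, self)

    def cdf(self, k) -> np.ndarray | float:
        return bb_cdf(k, self)

    @property
    def mean(self) -> float:
        return bb_mean(self)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a minimum-K-S beta-binomial fit.

    ``ks_stat`` is max_k |ECDF(k) - cdf(k)| of ``dist`` against the empirical
    distribution that was fitted; ``converged`` is False when the optimizer
    stalled or a shape parameter hit its bound.
    """

    dist: BetaBinomial
    ks_stat: float
    converged: bool
    n_total: float


def _log_beta(a, b):
    return gammaln(a) + gammaln(b) - gammaln(a + b)


def bb_pmf(k, dist: BetaBinomial):
    """Beta-binomial probability mass at tally ``k``.

    Evaluated entirely in log space (log-gamma, no raw factorials) so that
    ensembles of thousands of submodels pose no overflow problem.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > dist.K):
        raise ValueError(f"tally k must lie in 0..{dist.K}")
    K, a, b = dist.K, dist.alpha, dist.beta
    log_choose = gammaln(K + 1) - gammaln(k_arr + 1) - gammaln(K - k_arr + 1)
    log_p = log_choose + _log_beta(k_arr + a, K - k_arr + b) - _log_beta(a, b)
    out = np.exp(log_p)
    return out if out.ndim else float(out)


def bb_cdf(k, dist: BetaBinomial):
    """Cumulative beta-binomial probability P(tally <= k)."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > dist.K):
        raise ValueError(f"tally k must lie in 0..{dist.K}")
    cum = np.cumsum(bb_pmf(dist.support, dist))
    out = cum[k_arr.astype(int)]
    return out if np.asarray(k).ndim else float(out)


def bb_mean(dist: BetaBinomial) -> float:
    """Mean tally K * alpha / (alpha + beta)."""
    return dist.K * dist.alpha / (dist.alpha + dist.beta)


def binomial_pmf(k, K: int, p: float):
    """Binomial mass — the (unsatisfactory) independent-votes comparator."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > K):
        raise ValueError(f"tally k must lie in 0..{K}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_choose = gammaln(K + 1) - gammaln(k_arr + 1) - gammaln(K - k_arr + 1)
        log_p = log_choose + k_arr * np.log(p) + (K - k_arr) * np.log1p(-p)
    # 0*log(0) terms: define 0^0 = 1
    log_p = np.where(np.isnan(log_p), -np.inf, log_p)
    if p == 0:
        log_p = np.where(k_arr == 0, 0.0, -np.inf)
    elif p == 1:
        log_p = np.where(k_arr == K, 0.0, -np.inf)
    out = np.exp(log_p)
    return out if out.ndim else float(out)


def _ks_distance(counts: np.ndarray, dist: BetaBinomial) -> float:
    """sup_k |ECDF(k) - BBcdf(k)| over the shared discrete support 0..K."""
    ecdf = np.cumsum(counts) / counts.sum()
    return float(np.max(np.abs(ecdf - bb_cdf(dist.support, dist))))


def _moment_init(counts: np.ndarray, K: int) -> tuple[float, float]:
    """Method-of-moments (alpha, beta), clamped into [0.05, 100]."""
    k = np.arange(K + 1)
    n = counts.sum()
    m1 = float((k * counts).sum() / n)
    m2 = float((k**2 * counts).sum() / n)
    var = max(m2 - m1**2, 1e-12)
    p = m1 / K
    # binomial variance K p (1-p); excess variance sets the overdispersion
    denom = var / max(p * (1 - p), 1e-12) - 1.0
    if denom <= 0 or K <= 1:
        s = 100.0  # at/below binomial variance: nearly degenerate large shapes
    else:
        s = max((K - denom) / denom, 1e-6)
    alpha = np.clip(p * s, 0.05, 100.0)
    beta = np.clip((1 - p) * s, 0.05, 100.0)
    return float(alpha), float(beta)


def fit_betabinomial(counts) -> FitResult:
    """Fit (alpha, beta) to tally counts by minimizing the K-S statistic.

    Parameters
    ----------
    counts : array-like of shape (K+1,)
        Non-negative (possibly continuity-corrected, hence non-integer)
        counts per tally 0..K; must not be all zero.

    Returns
    -------
    FitResult
        Minimizer of max_k |ECDF(k) - cdf(k)| in (log alpha, log beta) by
        Nelder-Mead from a method-of-moments start, with a coarse log-grid
        fallback; deterministic for given counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("counts must be a 1-D array of length K+1 >= 2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("counts sum to zero; nothing to fit")
    K = counts.size - 1

    def objective(log_ab: np.ndarray) -> float:
        a, b = np.exp(log_ab)
        if not (_PARAM_LO <= a <= _PARAM_HI and _PARAM_LO <= b <= _PARAM_HI):
            return 2.0  # outside the admissible box; any K-S value is <= 1
        return _ks_distance(counts, BetaBinomial(K, a, b))

    a0, b0 = _moment_init(counts, K)
    x0 = np.log([a0, b0])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    best_x, best_f = res.x, res.fun

    init_f = objective(x0)
    if best_f > init_f - 1e-12 and best_f > 1e-9:
        # simplex stalled at (or above) the start: coarse log-grid restart
        grid = np.log(np.geomspace(0.05, 50.0, 25))
        gx = min(
            ((np.array([la, lb])) for la in grid for lb in grid),
            key=lambda x: objective(x),
        )
        res2 = minimize(
            objective,
            gx,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if res2.fun < best_f:
            best_x, best_f = res2.x, res2.fun

    alpha, beta = np.exp(best_x)
    alpha = float(np.clip(alpha, _PARAM_LO, _PARAM_HI))
    beta = float(np.clip(beta, _PARAM_LO, _PARAM_HI))
    at_bound = alpha in (_PARAM_LO, _PARAM_HI) or beta in (_PARAM_LO, _PARAM_HI)
    dist = BetaBinomial(K, alpha, beta)
    return FitResult(
        dist=dist,
        ks_stat=_ks_distance(counts, dist),
        converged=bool(res.success or best_f < init_f) and not at_bound,
        n_total=total,
    )
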