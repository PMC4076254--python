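"""Uncertainty profiles u(k) = MR * eps(k) / phi(k) and threshold refinement.

Writing P(err | k) for the probability that a prediction receiving k positive
votes is wrong, Bayes' theorem gives P(err | k) P(k) = P(k | err) P(err).
Estimating P(k) by a beta binomial phi(k) fitted to the training-pool
prediction tallies, P(k | err) by a beta binomial eps(k) fitted to the error
tallies, and P(err) by the raw misclassification rate MR yields the
uncertainty profile

    u(k) = MR * eps(k) / phi(k),

reported to users as confidence 1 - u(k).

For unbalanced data sets the Youden-placed thresholds produce a discontinuity
in the observed error rate at the decision threshold; shifting the voting
threshold to floor(mean of eps) + 0.5 (the half-integer guards against tied
votes) rebalances specificity against sensitivity.  For the averaging rule the
analogous refinement moves the summed-output threshold to the geometric mean
of the J_max threshold and the eps mean.  A composite profile stitches the
refined curve below the refined threshold to the naive curve above it.

A sound profile crosses its decision threshold near u = 0.5 (at the threshold
the ensemble is guessing); profiles crossing well below 0.4 flag unreliable
per-prediction confidences, for which the class-average fallbacks
1 - NPV / 1 - PPV are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .betabinom import BetaBinomial, FitResult, bb_mean, bb_pmf, fit_betabinomial
from .consensus import ConfusionStats, CountProfile

__all__ = [
    "UncertaintyProfile",
    "fit_profiles",
    "uncertainty_profile",
    "refine_voting_threshold",
    "refine_averaging_threshold",
    "composite_profile",
    "class_average_uncertainties",
    "reliability_check",
    "interpolate_at_threshold",
]

Diagnostic = Literal["ok", "warn", "unreliable"]

# a trustworthy profile crosses its threshold near 0.5; "well below" flags it
_WARN_CUT = 0.45
_UNRELIABLE_CUT = 0.40


@dataclass(frozen=True)
class UncertaintyProfile:
    """Per-tally uncertainty u(k) with its ingredients and diagnostics.

    ``u`` is clipped to [0, 1]; ``u_raw`` keeps the unclipped ratio
    MR * eps(k) / phi(k), which satisfies sum_k u_raw(k) phi(k) = MR exactly.
    """

    K: int
    MR: float
    phi: BetaBinomial
    eps: BetaBinomial
    u: np.ndarray
    u_raw: np.ndarray
    threshold: float
    method: Literal["voting", "averaging"] = "voting"
    diagnostic: Diagnostic | None = None

    @property
    def confidence(self) -> np.ndarray:
        return 1.0 - self.u

    def u_at(self, x: float) -> float:
        return interpolate_at_threshold(self.u, x)


def fit_profiles(corrected: CountProfile) -> tuple[FitResult, FitResult]:
    """Fit phi to corrected prediction counts and eps to corrected error counts."""
    if not corrected.corrected:
        raise ValueError("profiles are fitted to continuity-corrected counts")
    phi = fit_betabinomial(corrected.pred_counts)
    eps = fit_betabinomial(corrected.err_counts)
    return phi, eps


def uncertainty_profile(
    MR: float,
    phi: BetaBinomial,
    eps: BetaBinomial,
    threshold: float | None = None,
    method: Literal["voting", "averaging"] = "voting",
) -> UncertaintyProfile:
    """Assemble u(k) = MR * eps(k) / phi(k) over k = 0..K, clipped to [0, 1]."""
    if phi.K != eps.K:
        raise ValueError(f"phi (K={phi.K}) and eps (K={eps.K}) disagree on K")
    if not 0.0 <= MR <= 1.0:
        raise ValueError("MR must lie in [0, 1]")
    k = phi.support
    u_raw = MR * bb_pmf(k, eps) / bb_pmf(k, phi)
    profile = UncertaintyProfile(
        K=phi.K,
        MR=float(MR),
        phi=phi,
        eps=eps,
        u=np.clip(u_raw, 0.0, 1.0),
        u_raw=u_raw,
        threshold=float(threshold) if threshold is not None else float("nan"),
        method=method,
    )
    if threshold is not None:
        profile = replace(profile, diagnostic=reliability_check(profile))
    return profile


def refine_voting_threshold(eps: BetaBinomial) -> float:
    """Refined vote threshold floor(K * alpha / (alpha + beta)) + 0.5.

    The error distribution's mean marks where misclassifications concentrate;
    flooring and adding 0.5 yields a tie-proof half-integer threshold.
    """
    return math.floor(bb_mean(eps)) + 0.5


def refine_averaging_threshold(jmax_sum: float, eps_mean_sum: float) -> float:
    """Refined summed-output threshold sqrt(jmax_sum * eps_mean_sum).

    Both arguments live on the summed-output scale (per-network threshold
    times K).  Shifting all the way to the error-distribution mean
    overcorrects; the geometric mean with the J_max threshold does not.
    Divide by K for the per-network (averaging) scale.
    """
    if jmax_sum <= 0 or eps_mean_sum <= 0:
        raise ValueError("thresholds must be positive on the summed-output scale")
    return math.sqrt(jmax_sum * eps_mean_sum)


def composite_profile(
    u_naive: UncertaintyProfile,
    u_refined: UncertaintyProfile,
    refined_threshold: float,
) -> UncertaintyProfile:
    """Stitch refined u(k) below the refined threshold to naive u(k) above it.

    The refined curve describes negative predictions (k below the threshold)
    well; the naive curve describes positive predictions.  A half-integer
    threshold guarantees no tally sits on the boundary.
    """
    if u_naive.K != u_refined.K:
        raise ValueError("profiles disagree on K")
    k = np.arange(u_naive.K + 1)
    below = k < refined_threshold
    u = np.where(below, u_refined.u, u_naive.u)
    u_raw = np.where(below, u_refined.u_raw, u_naive.u_raw)
    profile = UncertaintyProfile(
        K=u_naive.K,
        MR=u_refined.MR,
        phi=u_refined.phi,
        eps=u_refined.eps,
        u=u,
        u_raw=u_raw,
        threshold=float(refined_threshold),
        method=u_refined.method,
    )
    return replace(profile, diagnostic=reliability_check(profile))


def class_average_uncertainties(stats: ConfusionStats) -> tuple[float, float]:
    """Aggregate fallback uncertainties (u0, u1) = (1 - NPV, 1 - PPV).

    The per-class averages are the appropriate report when the per-tally
    profile is flagged unreliable.  NaN propagates when a predictive value is
    undefined (no predictions of that class).
    """
    return 1.0 - stats.NPV, 1.0 - stats.PPV


def interpolate_at_threshold(u: np.ndarray, threshold: float) -> float:
    """u linearly interpolated at a real-valued threshold between tallies."""
    u = np.asarray(u, dtype=float)
    K = u.size - 1
    x = float(np.clip(threshold, 0, K))
    lo = int(math.floor(x))
    hi = min(lo + 1, K)
    frac = x - lo
    return float(u[lo] * (1 - frac) + u[hi] * frac)


def reliability_check(profile: UncertaintyProfile) -> Diagnostic:
    """Classify a profile by its interpolated u at the decision threshold.

    >= 0.45 -> "ok"; [0.40, 0.45) -> "warn"; < 0.40 -> "unreliable" (the
    crossing sits well below the 0.5 a well-placed threshold implies).
    For the averaging method the threshold is interpreted on the summed-output
    scale, where it is commensurate with tallies.
    """
    if not np.isfinite(profile.threshold):
        raise ValueError("profile has no threshold to check against")
    u_at = profile.u_at(profile.threshold)
    if u_at >= _WARN_CUT:
        return "ok"
    if u_at >= _UNRELIABLE_CUT:
        return "warn"
    return "unreliable"
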