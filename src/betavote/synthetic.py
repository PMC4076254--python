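"""Seeded generators for every input the pipeline consumes.

Three generators cover the three stages:

* :func:`simulate_bb_tallies` — tallies drawn from a known beta binomial
  (p ~ Beta(alpha, beta), k ~ Binomial(K, p)); the oracle for fit recovery.
* :func:`simulate_features` — two Gaussian classes in D dimensions with
  controllable imbalance and separation; feeds the ensemble trainer.
* :func:`simulate_correlated_votes` — a latent-Gaussian copula over submodel
  outputs: each compound carries a shared latent difficulty, each submodel
  adds an idiosyncratic one, and the mixture weight rho sets the inter-
  submodel correlation.  rho > 0 plus heterogeneous compound difficulty
  produces exactly the overdispersion (tally variance above binomial) that
  motivates the beta binomial.

Defaults emulate a balanced two-class screen judged by a 33-submodel
ensemble with moderately correlated submodels; class_ratio ~ 0.25 or ~ 0.12
reproduces the 1:3 and 1:7 imbalanced regimes.  All generators are pure
functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .consensus import VoteMatrix
from .ensemble import Dataset

__all__ = [
    "SimSpec",
    "simulate_bb_tallies",
    "simulate_features",
    "simulate_correlated_votes",
]


@dataclass(frozen=True)
class SimSpec:
    """Conditions for a synthetic two-class ensemble study.

    Parameters
    ----------
    n : int
        Number of compounds.
    K : int
        Number of submodels (default 33).
    class_ratio : float
        Fraction of positives in (0, 1); allocation is exact
        (round(n * ratio) positives), not binomial, for determinism.
    difficulty : float
        Separation of the two class score distributions in latent standard
        deviations; larger is easier.  2.0 gives realistic ~0.9 per-submodel
        accuracy.
    rho : float
        Inter-submodel correlation of the latent noise, in [0, 1).
    seed : int
        Seed for the generator's RNG stream.
    """

    n: int
    K: int = 33
    class_ratio: float = 0.5
    difficulty: float = 2.0
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must lie strictly between 0 and 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.difficulty < 0:
            raise ValueError("difficulty must be >= 0")
        if self.K < 2:
            raise ValueError("K must be >= 2")


def _labels(n: int, class_ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(n * ratio) positives, shuffled so any slice mixes classes."""
    n_pos = int(round(n * class_ratio))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return labels


def simulate_bb_tallies(n: int, K: int, alpha: float, beta: float, seed: int) -> np.ndarray:
    """Draw n tallies from BB(K, alpha, beta) by the Beta-Binomial mixture."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    p = rng.beta(alpha, beta, size=n)
    return rng.binomial(K, p)


def simulate_features(spec: SimSpec, dims: int = 2) -> Dataset:
    """Two Gaussian clusters separated along every axis by spec.difficulty.

    Unit-variance clusters centred at 0 and at difficulty/sqrt(dims) per
    axis, so the class-centroid distance equals ``difficulty`` regardless of
    dimensionality.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec.n, spec.class_ratio, rng)
    offset = spec.difficulty / np.sqrt(dims)
    features = rng.standard_normal((spec.n, dims)) + offset * labels[:, None]
    return Dataset(features=features, labels=labels)


def simulate_correlated_votes(spec: SimSpec) -> VoteMatrix:
    """Vote matrix with beta-binomial-like overdispersed tallies.

    Each compound n of class y gets a shared latent z_n ~ N(0, 1); submodel j
    sees s_nj = mu_y + sqrt(rho) * z_n + sqrt(1 - rho) * e_nj with
    e_nj ~ N(0, 1) and outputs g_nj = logistic(s_nj), where
    mu_1 = +difficulty/2 and mu_0 = -difficulty/2.  A submodel threshold of
    0.5 then votes positive iff s_nj > 0.  At rho = 0 the votes are
    conditionally independent given the class and tallies are binomial;
    rho > 0 makes per-compound success probabilities heterogeneous and the
    tallies overdisperse.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec.n, spec.class_ratio, rng)
    mu = spec.difficulty * (labels - 0.5)
    shared = rng.standard_normal(spec.n)
    idio = rng.standard_normal((spec.n, spec.K))
    latent = (
        mu[:, None]
        + np.sqrt(spec.rho) * shared[:, None]
        + np.sqrt(1.0 - spec.rho) * idio
    )
    return VoteMatrix(outputs=expit(latent), labels=labels)
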