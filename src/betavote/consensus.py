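"""Vote tallies, ensemble decision rules, confusion statistics, count profiles.

An ensemble of K submodels produces, for each compound, K outputs in [0, 1].
Comparing each output to a threshold yields a positive-vote tally k in 0..K.
Two decision rules are supported:

* ``voting`` — each submodel votes against its own threshold and the ensemble
  classifies positive when the tally exceeds a half-integer vote threshold
  (half-integers make ties impossible);
* ``averaging`` — the mean output is compared to a single ensemble threshold;
  tallies are still computed (each output against that same ensemble
  threshold) but serve only the uncertainty estimation, not the decision.

Count profiles f(k) (predictions per tally) and e(k) (errors per tally) are
the raw material for the beta-binomial fits; the continuity correction of
+1 prediction / +0.5 error per tally stabilizes sparsely populated bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "VoteMatrix",
    "CountProfile",
    "ConfusionStats",
    "youden_threshold",
    "confusion_stats",
    "tally_votes",
    "classify",
    "naive_vote_threshold",
    "count_profiles",
    "continuity_correct",
]

Method = Literal["voting", "averaging"]


@dataclass(frozen=True)
class VoteMatrix:
    """N x K submodel outputs plus true labels.

    ``outputs[n, j]`` is submodel j's output g in [0, 1] for compound n;
    ``labels`` are the true classes in {0, 1}; ``ids`` identify rows.
    """

    outputs: np.ndarray
    labels: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        outputs = np.asarray(self.outputs, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if outputs.ndim != 2 or outputs.shape[1] < 2:
            raise ValueError("outputs must be an N x K matrix with K >= 2")
        if np.any(outputs < 0) or np.any(outputs > 1):
            raise ValueError("submodel outputs must lie in [0, 1]")
        if labels.shape != (outputs.shape[0],):
            raise ValueError("labels must have one entry per row of outputs")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        ids = self.ids
        if ids is None:
            ids = np.arange(outputs.shape[0])
        ids = np.asarray(ids)
        if ids.shape != (outputs.shape[0],):
            raise ValueError("ids must have one entry per row")
        object.__setattr__(self, "outputs", outputs)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.outputs.shape[0]

    @property
    def K(self) -> int:
        return self.outputs.shape[1]


@dataclass(frozen=True)
class CountProfile:
    """Prediction counts f(k) and error counts e(k) per tally k = 0..K."""

    K: int
    pred_counts: np.ndarray
    err_counts: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        pred = np.asarray(self.pred_counts, dtype=float)
        err = np.asarray(self.err_counts, dtype=float)
        if pred.shape != (self.K + 1,) or err.shape != (self.K + 1,):
            raise ValueError("profiles must have length K+1")
        if np.any(pred < 0) or np.any(err < 0):
            raise ValueError("counts must be non-negative")
        if not self.corrected and np.any(err > pred):
            raise ValueError("raw error counts cannot exceed prediction counts")
        object.__setattr__(self, "pred_counts", pred)
        object.__setattr__(self, "err_counts", err)

    @property
    def contingent_rates(self) -> np.ndarray:
        """Observed error rate e(k)/f(k); NaN where f(k) = 0 (raw profiles)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.err_counts / self.pred_counts


@dataclass(frozen=True)
class ConfusionStats:
    """Truth-table summary; PPV/NPV are NaN when their denominator is zero."""

    sensitivity: float
    specificity: float
    J: float
    MR: float
    PPV: float
    NPV: float


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximizing Youden's index J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct sorted scores plus
    guards below the minimum and above the maximum, so the all-positive and
    all-negative cuts are reachable.  Classification is strict:
    score > threshold => positive.  Ties in J are broken toward the lowest
    threshold, making the result deterministic.

    Returns
    -------
    (threshold, J)
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to place a threshold")

    distinct = np.unique(scores)
    eps = max(1e-9, 1e-9 * (distinct[-1] - distinct[0]))
    candidates = np.concatenate(
        ([distinct[0] - eps], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + eps])
    )
    # vectorized J over all candidates
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    tp = (pos_scores[None, :] > candidates[:, None]).sum(axis=1)
    fp = (neg_scores[None, :] > candidates[:, None]).sum(axis=1)
    J = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    # lowest threshold whose J ties the maximum (to rounding)
    best = int(np.argmax(J > J.max() - 1e-12))
    return float(candidates[best]), float(J[best])


def confusion_stats(predicted, labels) -> ConfusionStats:
    """Sensitivity, specificity, J, misclassification rate, PPV and NPV.

    MR is computed from raw counts: (FP + FN) / N.
    """
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in labels")
    tp = int(((predicted == 1) & (labels == 1)).sum())
    fn = n_pos - tp
    tn = int(((predicted == 0) & (labels == 0)).sum())
    fp = n_neg - tn
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return ConfusionStats(
        sensitivity=sens,
        specificity=spec,
        J=sens + spec - 1.0,
        MR=(fp + fn) / labels.size,
        PPV=ppv,
        NPV=npv,
    )


def tally_votes(
    vm: VoteMatrix,
    mode: Method = "voting",
    net_thresholds=None,
    ensemble_threshold: float | None = None,
) -> np.ndarray:
    """Positive-vote tallies per compound.

    ``voting`` compares each submodel's output to that submodel's own
    threshold; ``averaging`` compares every output to the single ensemble
    threshold.  Comparisons are strictly greater-than.
    """
    if mode == "voting":
        if net_thresholds is None:
            raise ValueError("voting mode requires per-network thresholds")
        th = np.asarray(net_thresholds, dtype=float)
        if th.shape != (vm.K,):
            raise ValueError(f"expected {vm.K} per-network thresholds, got {th.shape}")
        return (vm.outputs > th[None, :]).sum(axis=1)
    elif mode == "averaging":
        if ensemble_threshold is None:
            raise ValueError("averaging mode requires an ensemble threshold")
        return (vm.outputs > float(ensemble_threshold)).sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def naive_vote_threshold(K: int) -> float:
    """Naive majority-rule vote threshold floor(K/2) + 0.5 (k > 16.5 at K=33)."""
    return float(K // 2) + 0.5


def classify(
    vm: VoteMatrix,
    mode: Method = "voting",
    tallies=None,
    vote_threshold: float | None = None,
    ensemble_threshold: float | None = None,
) -> np.ndarray:
    """Ensemble classification per compound (1 = positive).

    Voting: positive iff tally > vote_threshold, which must be a
    half-integer so that ties cannot occur.  Averaging: positive iff the mean
    submodel output strictly exceeds the ensemble threshold.
    """
    if mode == "voting":
        if tallies is None or vote_threshold is None:
            raise ValueError("voting mode requires tallies and a vote threshold")
        if float(vote_threshold) != int(vote_threshold) + 0.5:
            raise ValueError(
                f"vote threshold must be a half-integer (got {vote_threshold}); "
                "integer thresholds permit ties"
            )
        return (np.asarray(tallies) > float(vote_threshold)).astype(int)
    elif mode == "averaging":
        if ensemble_threshold is None:
            raise ValueError("averaging mode requires an ensemble threshold")
        return (vm.outputs.mean(axis=1) > float(ensemble_threshold)).astype(int)
    raise ValueError(f"unknown mode {mode!r}")


def count_profiles(tallies, correct, K: int) -> CountProfile:
    """Raw prediction and error counts per tally.

    ``correct`` flags each prediction as correct (True) or an error (False).
    """
    tallies = np.asarray(tallies, dtype=int)
    correct = np.asarray(correct, dtype=bool)
    if tallies.shape != correct.shape:
        raise ValueError("tallies and correct flags must have the same length")
    if tallies.size and (tallies.min() < 0 or tallies.max() > K):
        raise ValueError(f"tallies must lie in 0..{K}")
    pred = np.bincount(tallies, minlength=K + 1).astype(float)
    err = np.bincount(tallies[~correct], minlength=K + 1).astype(float)
    return CountProfile(K=K, pred_counts=pred, err_counts=err, corrected=False)


def continuity_correct(profile: CountProfile) -> CountProfile:
    """Apply the continuity correction: +1 per prediction bin, +0.5 per error bin.

    Empty bins then carry a contingent rate of 0.5/1 = 0.5; a single
    correct prediction 0.5/2 = 0.25; a single error 1.5/2 = 0.75.
    """
    if profile.corrected:
        raise ValueError("profile is already continuity-corrected")
    return replace(
        profile,
        pred_counts=profile.pred_counts + 1.0,
        err_counts=profile.err_counts + 0.5,
        corrected=True,
    )


def uncorrect(profile: CountProfile) -> CountProfile:
    """Invert :func:`continuity_correct`, recovering the raw profile."""
    if not profile.corrected:
        raise ValueError("profile is not continuity-corrected")
    return replace(
        profile,
        pred_counts=profile.pred_counts - 1.0,
        err_counts=profile.err_counts - 0.5,
        corrected=False,
    )
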