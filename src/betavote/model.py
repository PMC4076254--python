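"""Model / Results interface wiring the full vote-consensus protocol.

:class:`EnsembleUncertaintyModel` holds a vote matrix (submodel outputs plus
true labels for a training pool) together with the decision rule, and
``fit()`` executes the whole estimation protocol: tally votes, classify,
count predictions and errors per tally, continuity-correct, fit beta
binomials phi(k) and eps(k) by minimum K-S distance, and assemble the
uncertainty profile u(k) = MR * eps(k) / phi(k).  With ``refine=True`` the
decision threshold is additionally re-derived from the fitted error
distribution (voting: floor(mean) + 0.5; averaging: geometric mean of the
J_max and eps-mean summed thresholds), the affected distributions are
refitted, and a composite profile is stitched for the voting rule.

:class:`EnsembleUncertaintyResults` carries the estimates, a ``summary()``
table, ``predict()`` for scoring new compounds with the stored distributions
(no refitting), round-trip ``to_dict``/``from_dict`` serialization, and an
optional matplotlib profile plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .betabinom import BetaBinomial, FitResult, bb_mean, bb_pmf, fit_betabinomial
from .consensus import (
    ConfusionStats,
    CountProfile,
    VoteMatrix,
    classify,
    confusion_stats,
    continuity_correct,
    count_profiles,
    naive_vote_threshold,
    tally_votes,
    youden_threshold,
)
from .ensemble import Dataset, EnsembleModel, TrainConfig, train_ensemble
from .uncertainty import (
    UncertaintyProfile,
    class_average_uncertainties,
    composite_profile,
    fit_profiles,
    refine_averaging_threshold,
    refine_voting_threshold,
    uncertainty_profile,
)

__all__ = ["EnsembleUncertaintyModel", "EnsembleUncertaintyResults"]

Method = Literal["voting", "averaging"]


class EnsembleUncertaintyModel:
    """Vote-consensus uncertainty model for a binary ensemble classifier.

    Parameters
    ----------
    vote_matrix : VoteMatrix
        Training-pool submodel outputs and true labels.
    method : {"voting", "averaging"}
        Ensemble decision rule.
    net_thresholds : array-like, optional
        Per-submodel vote thresholds (voting method).  Default 0.5 each.
    ensemble_threshold : float, optional
        Threshold on the mean output (averaging method).  When omitted it is
        placed by maximizing Youden's J of the mean output on the pool (the
        J_max threshold).
    vote_threshold : float, optional
        Half-integer ensemble vote threshold (voting).  Default is naive
        majority rule, floor(K/2) + 0.5.
    ensemble : EnsembleModel, optional
        The trained submodels, kept for scoring feature data and
        serialization.
    """

    def __init__(
        self,
        vote_matrix: VoteMatrix,
        method: Method = "voting",
        net_thresholds=None,
        ensemble_threshold: float | None = None,
        vote_threshold: float | None = None,
        ensemble: EnsembleModel | None = None,
    ) -> None:
        self.vote_matrix = vote_matrix
        if method not in ("voting", "averaging"):
            raise ValueError(f"unknown method {method!r}")
        self.method: Method = method
        self.ensemble = ensemble
        K = vote_matrix.K
        if net_thresholds is None:
            net_thresholds = np.full(K, 0.5)
        self.net_thresholds = np.asarray(net_thresholds, dtype=float)
        if self.net_thresholds.shape != (K,):
            raise ValueError(f"expected {K} per-network thresholds")
        if ensemble_threshold is None and method == "averaging":
            ensemble_threshold, _ = youden_threshold(
                vote_matrix.outputs.mean(axis=1), vote_matrix.labels
            )
        self.ensemble_threshold = (
            float(ensemble_threshold) if ensemble_threshold is not None else None
        )
        self.vote_threshold = (
            float(vote_threshold)
            if vote_threshold is not None
            else naive_vote_threshold(K)
        )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, method: Method = "voting", **kwargs
    ) -> "EnsembleUncertaintyModel":
        """Build from a DataFrame with columns id, label, g_1..g_K."""
        g_cols = [c for c in df.columns if c.startswith("g_")]
        if not g_cols:
            raise ValueError("no submodel output columns (g_1..g_K) found")
        g_cols = sorted(g_cols, key=lambda c: int(c.split("_")[1]))
        vm = VoteMatrix(
            outputs=df[g_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            ids=df["id"].to_numpy() if "id" in df.columns else None,
        )
        return cls(vm, method=method, **kwargs)

    @classmethod
    def from_ensemble(
        cls,
        ensemble: EnsembleModel,
        pool: Dataset,
        method: Method = "voting",
    ) -> "EnsembleUncertaintyModel":
        """Build from a trained ensemble evaluated on its training pool."""
        vm = ensemble.vote_matrix(pool)
        return cls(
            vm,
            method=method,
            net_thresholds=ensemble.net_thresholds,
            ensemble_threshold=ensemble.ensemble_threshold,
            vote_threshold=ensemble.vote_threshold,
            ensemble=ensemble,
        )

    @classmethod
    def from_features(
        cls,
        pool: Dataset,
        config: TrainConfig,
        method: Method = "voting",
    ) -> "EnsembleUncertaintyModel":
        """Train the built-in ANN ensemble on the pool, then build the model."""
        return cls.from_ensemble(train_ensemble(pool, config), pool, method=method)

    # ------------------------------------------------------------------ #

    def _tally_and_classify(self, vm, ensemble_threshold=None, vote_threshold=None):
        if self.method == "voting":
            tallies = tally_votes(vm, "voting", net_thresholds=self.net_thresholds)
            predicted = classify(
                vm,
                "voting",
                tallies=tallies,
                vote_threshold=(
                    vote_threshold if vote_threshold is not None else self.vote_threshold
                ),
            )
        else:
            th = (
                ensemble_threshold
                if ensemble_threshold is not None
                else self.ensemble_threshold
            )
            tallies = tally_votes(vm, "averaging", ensemble_threshold=th)
            predicted = classify(vm, "averaging", ensemble_threshold=th)
        return tallies, predicted

    def fit(self, refine: bool = False) -> "EnsembleUncertaintyResults":
        """Run the estimation protocol on the training pool."""
        vm = self.vote_matrix
        K = vm.K
        tallies, predicted = self._tally_and_classify(vm)
        stats = confusion_stats(predicted, vm.labels)
        raw = count_profiles(tallies, predicted == vm.labels, K)
        corrected = continuity_correct(raw)
        phi_fit, eps_fit = fit_profiles(corrected)
        # diagnostic threshold lives on the tally scale: the vote threshold
        # for voting, the summed-output threshold for averaging
        naive_thr = (
            self.vote_threshold
            if self.method == "voting"
            else self.ensemble_threshold * K
        )
        naive = uncertainty_profile(
            stats.MR, phi_fit.dist, eps_fit.dist, threshold=naive_thr, method=self.method
        )
        res = EnsembleUncertaintyResults(
            model=self,
            tallies=tallies,
            predicted=predicted,
            stats=stats,
            raw_profile=raw,
            corrected_profile=corrected,
            phi_fit=phi_fit,
            eps_fit=eps_fit,
            profile=naive,
        )
        if refine:
            self._refine(res)
        return res

    def _refine(self, res: "EnsembleUncertaintyResults") -> None:
        vm = self.vote_matrix
        K = vm.K
        if self.method == "voting":
            # shifting the vote threshold re-labels ensemble decisions but
            # leaves tallies, hence phi, untouched
            new_thr = refine_voting_threshold(res.eps_fit.dist)
            predicted = classify(
                vm, "voting", tallies=res.tallies, vote_threshold=new_thr
            )
            stats = confusion_stats(predicted, vm.labels)
            raw = count_profiles(res.tallies, predicted == vm.labels, K)
            corrected = continuity_correct(raw)
            eps_fit = fit_betabinomial(corrected.err_counts)
            refined = uncertainty_profile(
                stats.MR, res.phi_fit.dist, eps_fit.dist, threshold=new_thr
            )
            res.refined_threshold = new_thr
            res.refined_predicted = predicted
            res.refined_stats = stats
            res.refined_raw_profile = raw
            res.refined_corrected_profile = corrected
            res.refined_phi_fit = res.phi_fit  # unchanged by construction
            res.refined_eps_fit = eps_fit
            res.refined_profile = refined
            res.composite = composite_profile(res.profile, refined, new_thr)
        else:
            jmax_sum = self.ensemble_threshold * K
            eps_mean_sum = bb_mean(res.eps_fit.dist)
            new_sum = refine_averaging_threshold(jmax_sum, eps_mean_sum)
            new_theta = new_sum / K
            tallies, predicted = self._tally_and_classify(
                vm, ensemble_threshold=new_theta
            )
            stats = confusion_stats(predicted, vm.labels)
            raw = count_profiles(tallies, predicted == vm.labels, K)
            corrected = continuity_correct(raw)
            phi_fit, eps_fit = fit_profiles(corrected)
            refined = uncertainty_profile(
                stats.MR,
                phi_fit.dist,
                eps_fit.dist,
                threshold=new_sum,
                method="averaging",
            )
            res.refined_threshold = new_sum
            res.refined_ensemble_threshold = new_theta
            res.refined_tallies = tallies
            res.refined_predicted = predicted
            res.refined_stats = stats
            res.refined_raw_profile = raw
            res.refined_corrected_profile = corrected
            res.refined_phi_fit = phi_fit
            res.refined_eps_fit = eps_fit
            res.refined_profile = refined
            res.composite = None  # averaging profiles lack the discontinuity


@dataclass
class EnsembleUncertaintyResults:
    """Fitted uncertainty estimates for an ensemble classification model."""

    model: EnsembleUncertaintyModel
    tallies: np.ndarray
    predicted: np.ndarray
    stats: ConfusionStats
    raw_profile: CountProfile
    corrected_profile: CountProfile
    phi_fit: FitResult
    eps_fit: FitResult
    profile: UncertaintyProfile
    # populated by fit(refine=True)
    refined_threshold: float | None = None
    refined_ensemble_threshold: float | None = None
    refined_tallies: np.ndarray | None = None
    refined_predicted: np.ndarray | None = None
    refined_stats: ConfusionStats | None = None
    refined_raw_profile: CountProfile | None = None
    refined_corrected_profile: CountProfile | None = None
    refined_phi_fit: FitResult | None = None
    refined_eps_fit: FitResult | None = None
    refined_profile: UncertaintyProfile | None = None
    composite: UncertaintyProfile | None = None

    # ------------------------------------------------------------------ #

    @property
    def K(self) -> int:
        return self.model.vote_matrix.K

    @property
    def MR(self) -> float:
        return self.stats.MR

    @property
    def refined(self) -> bool:
        return self.refined_profile is not None

    @property
    def active_profile(self) -> UncertaintyProfile:
        """The profile used for scoring: composite > refined > naive."""
        if self.composite is not None:
            return self.composite
        if self.refined_profile is not None:
            return self.refined_profile
        return self.profile

    @property
    def diagnostic(self) -> str:
        return self.active_profile.diagnostic

    @property
    def class_uncertainties(self) -> tuple[float, float]:
        """(u0, u1) = (1 - NPV, 1 - PPV) aggregate fallbacks."""
        stats = self.refined_stats if self.refined else self.stats
        return class_average_uncertainties(stats)

    # ------------------------------------------------------------------ #

    def predict(self, data) -> pd.DataFrame:
        """Score new compounds with the stored distributions (no refitting).

        ``data`` is a VoteMatrix, an N x K output matrix, or a Dataset (the
        latter requires the trained ensemble to be attached).  Returns one
        row per compound: id, tally, classification, u, confidence.
        """
        model = self.model
        if isinstance(data, Dataset):
            if model.ensemble is None:
                raise ValueError("scoring feature data requires a trained ensemble")
            outputs = model.ensemble.outputs(data.features)
            labels = data.labels
            ids = np.arange(len(labels))
        elif isinstance(data, VoteMatrix):
            outputs, labels, ids = data.outputs, data.labels, data.ids
        else:
            outputs = np.asarray(data, dtype=float)
            labels = None
            ids = np.arange(outputs.shape[0])
        if outputs.shape[1] != self.K:
            raise ValueError(
                f"model expects K={self.K} submodel outputs, got {outputs.shape[1]}"
            )
        vm_like = VoteMatrix(
            outputs=outputs,
            labels=labels if labels is not None else np.zeros(len(outputs), dtype=int),
            ids=ids,
        )
        if model.method == "voting":
            tallies = tally_votes(vm_like, "voting", net_thresholds=model.net_thresholds)
            thr = self.refined_threshold if self.refined else model.vote_threshold
            predicted = classify(vm_like, "voting", tallies=tallies, vote_threshold=thr)
        else:
            theta = (
                self.refined_ensemble_threshold
                if self.refined
                else model.ensemble_threshold
            )
            tallies = tally_votes(vm_like, "averaging", ensemble_threshold=theta)
            predicted = classify(vm_like, "averaging", ensemble_threshold=theta)
        u = self.active_profile.u[tallies]
        return pd.DataFrame(
            {
                "id": ids,
                "tally": tallies,
                "classification": predicted,
                "u": u,
                "confidence": 1.0 - u,
            }
        )

    def profile_frame(self, which: str = "active") -> pd.DataFrame:
        """Per-tally table: k, phi_pmf, eps_pmf, u, confidence."""
        prof = {
            "active": self.active_profile,
            "naive": self.profile,
            "refined": self.refined_profile,
            "composite": self.composite,
        }[which]
        if prof is None:
            raise ValueError(f"no {which!r} profile on this result")
        k = np.arange(self.K + 1)
        return pd.DataFrame(
            {
                "k": k,
                "phi_pmf": bb_pmf(k, prof.phi),
                "eps_pmf": bb_pmf(k, prof.eps),
                "u": prof.u,
                "confidence": prof.confidence,
            }
        )

    def summary(self) -> str:
        """Human-readable estimation summary."""
        m = self.model
        u0, u1 = self.class_uncertainties
        lines = [
            "Ensemble classification uncertainty (beta-binomial consensus model)",
            "=" * 68,
            f"Method: {m.method}    K = {self.K} submodels    "
            f"N = {m.vote_matrix.n} pool predictions",
            f"Decision threshold: "
            + (
                f"{m.vote_threshold:g} votes"
                if m.method == "voting"
                else f"{m.ensemble_threshold:.4f} (mean output); "
                f"{m.ensemble_threshold * self.K:.1f} (summed)"
            ),
            "-" * 68,
            f"MR (misclassification rate) : {self.MR:.4f}",
            f"sensitivity / specificity   : {self.stats.sensitivity:.4f} / "
            f"{self.stats.specificity:.4f}   (J = {self.stats.J:.4f})",
            f"phi(k)  alpha, beta         : {self.phi_fit.dist.alpha:.4f}, "
            f"{self.phi_fit.dist.beta:.4f}   (K-S {self.phi_fit.ks_stat:.4f})",
            f"eps(k)  alpha, beta         : {self.eps_fit.dist.alpha:.4f}, "
            f"{self.eps_fit.dist.beta:.4f}   (K-S {self.eps_fit.ks_stat:.4f})",
            f"eps mean (tally scale)      : {bb_mean(self.eps_fit.dist):.2f}",
        ]
        if self.refined:
            rs = self.refined_stats
            lines += [
                "-" * 68,
                f"refined threshold           : {self.refined_threshold:g}"
                + (
                    f"  (mean-output {self.refined_ensemble_threshold:.4f})"
                    if self.refined_ensemble_threshold is not None
                    else ""
                ),
                f"refined MR                  : {rs.MR:.4f}",
                f"refined sens / spec         : {rs.sensitivity:.4f} / "
                f"{rs.specificity:.4f}",
                f"refined eps alpha, beta     : {self.refined_eps_fit.dist.alpha:.4f}, "
                f"{self.refined_eps_fit.dist.beta:.4f}",
            ]
        lines += [
            "-" * 68,
            f"u at threshold (interp.)    : "
            f"{self.active_profile.u_at(self.active_profile.threshold):.4f}",
            f"diagnostic                  : {self.diagnostic}",
            f"class-average u0, u1        : {u0:.4f}, {u1:.4f}   "
            "(1-NPV, 1-PPV fallbacks)",
            "=" * 68,
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Plot count distributions, fitted beta binomials and u(k).

        Requires matplotlib. Returns the axes (counts on a log scale on the
        left axis, uncertainty on the right axis).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        k = np.arange(self.K + 1)
        n = self.raw_profile.pred_counts.sum()
        ax.semilogy(k, self.corrected_profile.pred_counts, "o-", color="tab:blue",
                    label="predictions (corrected)")
        ax.semilogy(k, self.corrected_profile.err_counts, "o-", color="tab:red",
                    label="errors (corrected)")
        ax.semilogy(k, n * bb_pmf(k, self.phi_fit.dist), "--", color="tab:blue",
                    label="fitted phi")
        e_tot = self.corrected_profile.err_counts.sum()
        ax.semilogy(k, e_tot * bb_pmf(k, self.eps_fit.dist), "--", color="tab:red",
                    label="fitted eps")
        ax.axvline(self.profile.threshold, color="k", ls=":", lw=1)
        ax2 = ax.twinx()
        ax2.plot(k, self.active_profile.u, "k--", label="u(k)")
        ax2.axhline(0.5, color="gray", ls=":", lw=1)
        ax2.set_ylim(0, 1.05)
        ax2.set_ylabel("uncertainty u(k)")
        ax.set_xlabel("positive-vote tally k")
        ax.set_ylabel("count")
        ax.legend(loc="upper center", fontsize=8)
        return ax

    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        """JSON-serializable state sufficient for scoring new data."""
        m = self.model

        def _bb(fit: FitResult | None):
            if fit is None:
                return None
            return {
                "alpha": fit.dist.alpha,
                "beta": fit.dist.beta,
                "K": fit.dist.K,
                "ks_stat": fit.ks_stat,
                "converged": fit.converged,
                "n_total": fit.n_total,
            }

        state = {
            "method": m.method,
            "K": self.K,
            "MR": self.MR,
            "net_thresholds": m.net_thresholds.tolist(),
            "ensemble_threshold": m.ensemble_threshold,
            "vote_threshold": m.vote_threshold,
            "phi": _bb(self.phi_fit),
            "eps": _bb(self.eps_fit),
            "threshold": self.profile.threshold,
            "refined_threshold": self.refined_threshold,
            "refined_ensemble_threshold": self.refined_ensemble_threshold,
            "refined_MR": self.refined_stats.MR if self.refined else None,
            "refined_phi": _bb(self.refined_phi_fit),
            "refined_eps": _bb(self.refined_eps_fit),
            "diagnostic": self.diagnostic,
            "u": self.profile.u.tolist(),
            "u_active": self.active_profile.u.tolist(),
            "class_uncertainties": list(self.class_uncertainties),
            "stats": {
                "sensitivity": self.stats.sensitivity,
                "specificity": self.stats.specificity,
                "J": self.stats.J,
                "MR": self.stats.MR,
                "PPV": self.stats.PPV,
                "NPV": self.stats.NPV,
            },
        }
        if m.ensemble is not None:
            state["ensemble"] = _ensemble_to_dict(m.ensemble)
        return state


def _ensemble_to_dict(ens: EnsembleModel) -> dict:
    return {
        "method": ens.method,
        "vote_threshold": ens.vote_threshold,
        "ensemble_threshold": ens.ensemble_threshold,
        "seed": ens.config.seed if ens.config else None,
        "config": (
            {
                "n_candidates": ens.config.n_candidates,
                "n_keep": ens.config.n_keep,
                "n_neurons": ens.config.n_neurons,
                "train_fraction": ens.config.train_fraction,
                "patience": ens.config.patience,
                "max_iters": ens.config.max_iters,
                "learning_rate": ens.config.learning_rate,
                "seed": ens.config.seed,
            }
            if ens.config
            else None
        ),
        "networks": [
            {
                "input_weights": net.input_weights.tolist(),
                "neuron_offsets": net.neuron_offsets.tolist(),
                "output_weights": net.output_weights.tolist(),
                "output_offset": net.output_offset,
                "net_threshold": net.net_threshold,
            }
            for net in ens.networks
        ],
    }


def score_with_state(state: dict, data) -> pd.DataFrame:
    """Score compounds using a serialized model state (no refitting).

    ``data`` is a VoteMatrix, an N x K output matrix, or a Dataset (needs
    ensemble weights in the state).  Per-tally u values come straight from
    the stored active profile.
    """
    K = int(state["K"])
    if isinstance(data, Dataset):
        if "ensemble" not in state:
            raise ValueError("state carries no ensemble weights; supply outputs")
        ens = ensemble_from_dict(state["ensemble"])
        outputs = ens.outputs(data.features)
        ids = np.arange(len(outputs))
    elif isinstance(data, VoteMatrix):
        outputs, ids = data.outputs, data.ids
    else:
        outputs = np.asarray(data, dtype=float)
        ids = np.arange(outputs.shape[0])
    if outputs.shape[1] != K:
        raise ValueError(f"model expects K={K} submodel outputs, got {outputs.shape[1]}")
    refined = state.get("refined_threshold") is not None
    if state["method"] == "voting":
        th = np.asarray(state["net_thresholds"], dtype=float)
        tallies = (outputs > th[None, :]).sum(axis=1)
        vote_thr = state["refined_threshold"] if refined else state["vote_threshold"]
        predicted = (tallies > float(vote_thr)).astype(int)
    else:
        theta = (
            state["refined_ensemble_threshold"] if refined else state["ensemble_threshold"]
        )
        tallies = (outputs > float(theta)).sum(axis=1)
        predicted = (outputs.mean(axis=1) > float(theta)).astype(int)
    u = np.asarray(state["u_active"], dtype=float)[tallies]
    return pd.DataFrame(
        {
            "id": ids,
            "tally": tallies,
            "classification": predicted,
            "u": u,
            "confidence": 1.0 - u,
        }
    )


def ensemble_from_dict(state: dict) -> EnsembleModel:
    from .ensemble import NetworkModel

    cfg = TrainConfig(**state["config"]) if state.get("config") else None
    return EnsembleModel(
        networks=[
            NetworkModel(
                input_weights=np.array(n["input_weights"]),
                neuron_offsets=np.array(n["neuron_offsets"]),
                output_weights=np.array(n["output_weights"]),
                output_offset=n["output_offset"],
                net_threshold=n["net_threshold"],
            )
            for n in state["networks"]
        ],
        method=state.get("method", "voting"),
        vote_threshold=state.get("vote_threshold"),
        ensemble_threshold=state.get("ensemble_threshold"),
        config=cfg,
    )
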