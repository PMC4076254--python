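"""Minimal single-hidden-layer neural-network ensemble trainer.

Each submodel is a one-hidden-layer tanh network with a logistic output,

    f_j = tanh( sum_i w_ij x_i - t_j ),      g = logistic( sum_j a_j f_j - b ),

trained by full-batch gradient descent on the class-weighted squared loss

    Obj = sum_l [ c0 (1 - q_l) g_l^2  +  c1 q_l (1 - g_l)^2 ],

where q_l is the 0/1 class indicator, c0 the fraction of positives and c1 the
fraction of negatives (so the smaller class carries the larger weight).
Early stopping monitors the same objective on a held-out verification third of
the training pool: training halts when it fails to improve for ``patience``
consecutive epochs and the best-verification weights are returned.  Each
network then gets its own classification threshold maximizing Youden's J on
its training set.

An ensemble trains ``n_candidates`` such networks on independent seeded
2/3 - 1/3 splits of the shared pool and keeps the ``n_keep`` with the best
(lowest) combined training + verification objective.  Every stochastic choice
flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .consensus import VoteMatrix, youden_threshold

__all__ = [
    "Dataset",
    "NetworkModel",
    "TrainConfig",
    "EnsembleModel",
    "network_forward",
    "objective",
    "class_weights",
    "train_network",
    "train_ensemble",
    "input_gradient_ranking",
    "filter_descriptors",
]


@dataclass(frozen=True)
class Dataset:
    """Feature matrix (N x D) with binary labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if features.ndim != 2:
            raise ValueError("features must be an N x D matrix")
        if labels.shape != (features.shape[0],):
            raise ValueError("labels must have one entry per row")
        if not np.isfinite(features).all():
            raise ValueError("features must be finite (no missing values)")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.features[idx], self.labels[idx])


@dataclass
class NetworkModel:
    """One trained submodel: weights, offsets, and its own vote threshold."""

    input_weights: np.ndarray  # D x H
    neuron_offsets: np.ndarray  # H
    output_weights: np.ndarray  # H
    output_offset: float
    net_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.neuron_offsets = np.asarray(self.neuron_offsets, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        h = self.input_weights.shape[1]
        if self.neuron_offsets.shape != (h,) or self.output_weights.shape != (h,):
            raise ValueError("inconsistent hidden-layer dimensions")
        if not 0.0 < self.net_threshold < 1.0:
            raise ValueError("net_threshold must lie strictly in (0, 1)")

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Ensemble training configuration; every random choice flows from seed."""

    n_candidates: int = 165
    n_keep: int = 33
    n_neurons: int = 3
    train_fraction: float = 2.0 / 3.0
    patience: int = 15
    max_iters: int = 500
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keep > self.n_candidates:
            raise ValueError("n_keep cannot exceed n_candidates")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EnsembleModel:
    """The kept submodels plus the ensemble decision rule."""

    networks: list[NetworkModel]
    method: str = "voting"
    vote_threshold: float | None = None  # half-integer, voting method
    ensemble_threshold: float | None = None  # averaging method
    config: TrainConfig | None = None

    @property
    def K(self) -> int:
        return len(self.networks)

    @property
    def net_thresholds(self) -> np.ndarray:
        return np.array([net.net_threshold for net in self.networks])

    def outputs(self, features: np.ndarray) -> np.ndarray:
        """N x K matrix of submodel outputs g."""
        features = np.asarray(features, dtype=float)
        return np.column_stack([network_forward(features, net) for net in self.networks])

    def vote_matrix(self, data: Dataset, ids=None) -> VoteMatrix:
        return VoteMatrix(outputs=self.outputs(data.features), labels=data.labels, ids=ids)


def network_forward(x, net: NetworkModel):
    """Network output g = logistic(sum_j a_j tanh(w_.j . x - t_j) - b).

    Accepts a single feature vector or an N x D matrix; returns a float or a
    length-N vector accordingly.
    """
    x_arr = np.atleast_2d(np.asarray(x, dtype=float))
    if x_arr.shape[1] != net.n_inputs:
        raise ValueError(
            f"expected {net.n_inputs} features, got {x_arr.shape[1]}"
        )
    hidden = np.tanh(x_arr @ net.input_weights - net.neuron_offsets)
    g = expit(hidden @ net.output_weights - net.output_offset)
    return g if np.asarray(x).ndim == 2 else float(g[0])


def class_weights(labels) -> tuple[float, float]:
    """(c0, c1) = (fraction of positives, fraction of negatives).

    c0 multiplies the negative-class error term and c1 the positive-class
    term, so the smaller class carries the larger weight.
    """
    labels = np.asarray(labels)
    c0 = float((labels == 1).mean())
    return c0, 1.0 - c0


def objective(outputs, labels, c0: float, c1: float) -> float:
    """Class-weighted squared loss sum c0 (1-q) g^2 + c1 q (1-g)^2."""
    g = np.asarray(outputs, dtype=float)
    q = np.asarray(labels, dtype=float)
    if g.shape != q.shape:
        raise ValueError("outputs and labels must have the same length")
    if c0 < 0 or c1 < 0:
        raise ValueError("class weights must be non-negative")
    return float(np.sum(c0 * (1 - q) * g**2 + c1 * q * (1 - g) ** 2))


def _forward_full(net: NetworkModel, X: np.ndarray):
    pre = X @ net.input_weights - net.neuron_offsets
    hidden = np.tanh(pre)
    g = expit(hidden @ net.output_weights - net.output_offset)
    return hidden, g


def _gradients(net: NetworkModel, X: np.ndarray, q: np.ndarray, c0: float, c1: float):
    """Analytic gradients of the objective w.r.t. (w, t, a, b)."""
    hidden, g = _forward_full(net, X)
    # dObj/dg then chain through the logistic
    dg = 2.0 * (c0 * (1 - q) * g - c1 * q * (1 - g))
    ds = dg * g * (1 - g)  # s = a.f - b
    grad_a = hidden.T @ ds
    grad_b = -float(ds.sum())
    dh = np.outer(ds, net.output_weights) * (1 - hidden**2)
    grad_w = X.T @ dh
    grad_t = -dh.sum(axis=0)
    return grad_w, grad_t, grad_a, grad_b, g


def _init_network(d: int, h: int, rng: np.random.Generator) -> NetworkModel:
    return NetworkModel(
        input_weights=rng.uniform(-0.5, 0.5, size=(d, h)),
        neuron_offsets=rng.uniform(-0.5, 0.5, size=h),
        output_weights=rng.uniform(-0.5, 0.5, size=h),
        output_offset=float(rng.uniform(-0.5, 0.5)),
    )


def train_network(
    train: Dataset, verify: Dataset, cfg: TrainConfig, seed: int
) -> NetworkModel:
    """Train one submodel with early stopping on the verification objective.

    Full-batch gradient descent; one iteration is one epoch.  The weights
    returned are those achieving the best verification objective.  The
    network's threshold is then placed by Youden's J on the *training* set.
    """
    for name, ds in (("training", train), ("verification", verify)):
        if len(np.unique(ds.labels)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    rng = np.random.default_rng(seed)
    net = _init_network(train.d, cfg.n_neurons, rng)
    c0, c1 = class_weights(train.labels)
    q_tr = train.labels.astype(float)
    q_ve = verify.labels.astype(float)

    def verify_obj(model: NetworkModel) -> float:
        _, g = _forward_full(model, verify.features)
        return objective(g, q_ve, c0, c1)

    best = _copy_net(net)
    best_obj = verify_obj(net)
    stall = 0
    lr = cfg.learning_rate / max(train.n, 1)  # per-sample scaling
    for _ in range(cfg.max_iters):
        grad_w, grad_t, grad_a, grad_b, _ = _gradients(
            net, train.features, q_tr, c0, c1
        )
        net.input_weights -= lr * grad_w
        net.neuron_offsets -= lr * grad_t
        net.output_weights -= lr * grad_a
        net.output_offset -= lr * grad_b
        vo = verify_obj(net)
        if vo < best_obj - 1e-12:
            best, best_obj, stall = _copy_net(net), vo, 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    _, g_train = _forward_full(best, train.features)
    threshold, _ = youden_threshold(g_train, train.labels)
    best.net_threshold = float(np.clip(threshold, 1e-9, 1 - 1e-9))
    return best


def _copy_net(net: NetworkModel) -> NetworkModel:
    return NetworkModel(
        input_weights=net.input_weights.copy(),
        neuron_offsets=net.neuron_offsets.copy(),
        output_weights=net.output_weights.copy(),
        output_offset=net.output_offset,
        net_threshold=net.net_threshold,
    )


def _candidate_score(net: NetworkModel, train: Dataset, verify: Dataset) -> float:
    """Selection score: c-weighted objective over training + verification."""
    c0, c1 = class_weights(np.concatenate([train.labels, verify.labels]))
    _, g_tr = _forward_full(net, train.features)
    _, g_ve = _forward_full(net, verify.features)
    return objective(g_tr, train.labels, c0, c1) + objective(
        g_ve, verify.labels, c0, c1
    )


def _stratified_split(pool: Dataset, frac: float, rng: np.random.Generator):
    """Class-stratified train/verify split so both subsets keep both classes."""
    idx_train, idx_verify = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(pool.labels == cls)
        rng.shuffle(idx)
        n_tr = max(1, min(len(idx) - 1, int(round(frac * len(idx)))))
        idx_train.append(idx[:n_tr])
        idx_verify.append(idx[n_tr:])
    return np.concatenate(idx_train), np.concatenate(idx_verify)


def train_ensemble(pool: Dataset, cfg: TrainConfig) -> EnsembleModel:
    """Train n_candidates submodels and keep the n_keep best.

    Each candidate gets an independent seeded stratified 2/3 - 1/3 split of
    the pool.  Candidates are ranked by the combined training + verification
    objective (lower is better, ties broken by candidate index).  The
    returned ensemble carries the naive majority vote threshold and the
    J_max averaging threshold on the pool.
    """
    if pool.n < 20:
        raise ValueError("training pool too small (need >= 20 observations)")
    if len(np.unique(pool.labels)) < 2:
        raise ValueError("training pool must contain both classes")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_candidates)
    scored: list[tuple[float, int, NetworkModel]] = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        tr_idx, ve_idx = _stratified_split(pool, cfg.train_fraction, rng)
        train, verify = pool.subset(tr_idx), pool.subset(ve_idx)
        net = train_network(train, verify, cfg, seed=ss.spawn(1)[0])
        scored.append((_candidate_score(net, train, verify), i, net))
    scored.sort(key=lambda t: (t[0], t[1]))
    kept = [net for _, _, net in scored[: cfg.n_keep]]
    model = EnsembleModel(networks=kept, method="voting", config=cfg)
    K = model.K
    model.vote_threshold = float(K // 2) + 0.5
    mean_out = np.column_stack(
        [_forward_full(net, pool.features)[1] for net in kept]
    ).mean(axis=1)
    model.ensemble_threshold, _ = youden_threshold(mean_out, pool.labels)
    return model


def input_gradient_ranking(net: NetworkModel, data: Dataset) -> np.ndarray:
    """Descriptor indices ranked by mean |dg/dx_i| over the rows, descending.

    The analytic sensitivity gradient of the network output with respect to
    each input is dg/dx_i = g (1 - g) sum_j a_j (1 - f_j^2) w_ij.  Ties keep
    input order (stable sort).
    """
    hidden, g = _forward_full(net, data.features)
    back = (g * (1 - g))[:, None] * ((1 - hidden**2) * net.output_weights)
    grads = back @ net.input_weights.T  # N x D
    mean_abs = np.abs(grads).mean(axis=0) if data.n else np.zeros(net.n_inputs)
    return np.argsort(-mean_abs, kind="stable")


def filter_descriptors(
    features: np.ndarray,
    cv_min: float = 0.01,
    min_nonzero: int = 4,
    corr_max: float = 0.98,
) -> np.ndarray:
    """Indices of descriptors passing the variation / sparsity / collinearity cuts.

    Drops descriptors whose coefficient of variation is below ``cv_min``,
    that are nonzero in fewer than ``min_nonzero`` cases, or whose absolute
    correlation with an earlier-kept descriptor exceeds ``corr_max``.
    """
    X = np.asarray(features, dtype=float)
    keep = []
    for i in range(X.shape[1]):
        col = X[:, i]
        mean = col.mean()
        cv = np.inf if mean == 0 else col.std() / abs(mean)
        if cv < cv_min:
            continue
        if np.count_nonzero(col) < min_nonzero:
            continue
        collinear = False
        for j in keep:
            other = X[:, j]
            if col.std() == 0 or other.std() == 0:
                continue
            r = np.corrcoef(col, other)[0, 1]
            if abs(r) > corr_max:
                collinear = True
                break
        if not collinear:
            keep.append(i)
    return np.asarray(keep, dtype=int)
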