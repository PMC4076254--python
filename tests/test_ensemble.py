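"""Single-hidden-layer ANN ensemble: forward pass, objective, training."""

import numpy as np
import pytest

from betavote import (
    Dataset,
    NetworkModel,
    SimSpec,
    TrainConfig,
    input_gradient_ranking,
    network_forward,
    objective,
    simulate_features,
    train_ensemble,
    train_network,
    youden_threshold,
)
from betavote.ensemble import _gradients, class_weights, filter_descriptors


def tiny_net(w, t, a, b, threshold=0.5):
    return NetworkModel(
        input_weights=np.atleast_2d(w).astype(float),
        neuron_offsets=np.atleast_1d(t).astype(float),
        output_weights=np.atleast_1d(a).astype(float),
        output_offset=float(b),
        net_threshold=threshold,
    )


class TestForward:
    def test_zero_network_outputs_half(self):
        net = tiny_net([[0.0, 0.0]], [0.0, 0.0], [0.0, 0.0], 0.0)
        assert network_forward(np.array([3.0]), net) == 0.5

    def test_hand_arithmetic(self):
        # logistic(tanh(1)) with a single neuron and unit weights
        net = tiny_net([[1.0]], [0.0], [1.0], 0.0)
        assert network_forward(np.array([1.0]), net) == pytest.approx(0.6816, abs=1e-4)

    def test_monotone_in_offset(self):
        x = np.array([0.7])
        outs = [
            network_forward(x, tiny_net([[1.0]], [0.0], [1.0], b))
            for b in (1.0, 0.0, -1.0)
        ]
        assert outs[0] < outs[1] < outs[2]

    def test_dimension_mismatch(self):
        net = tiny_net([[1.0]], [0.0], [1.0], 0.0)
        with pytest.raises(ValueError):
            network_forward(np.array([1.0, 2.0]), net)


class TestObjective:
    def test_perfect_outputs_zero_loss(self):
        assert objective([0.0, 1.0, 1.0], [0, 1, 1], 0.4, 0.6) == 0.0

    def test_half_outputs(self):
        assert objective([0.5] * 4, [0, 0, 1, 1], 0.5, 0.5) == pytest.approx(0.5)

    def test_smaller_class_gets_larger_weight(self):
        # 1 positive to 3 negatives: c0 (the negative-term weight) = 0.25,
        # c1 (the positive-term weight) = 0.75
        c0, c1 = class_weights([1, 0, 0, 0])
        assert (c0, c1) == (0.25, 0.75)
        assert c1 > c0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            objective([0.5], [0, 1], 0.5, 0.5)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        # central differences at 1e-5 on random small networks
        for _ in range(5):
            d, h, n = 3, 2, 6
            net = tiny_net(
                rng.uniform(-1, 1, (d, h)),
                rng.uniform(-1, 1, h),
                rng.uniform(-1, 1, h),
                rng.uniform(-1, 1),
            )
            X = rng.uniform(-1, 1, (n, d))
            q = rng.integers(0, 2, n).astype(float)
            gw, gt, ga, gb, _ = _gradients(net, X, q, 0.4, 0.6)

            def loss(model):
                return objective(network_forward(X, model), q, 0.4, 0.6)

            eps = 1e-5
            for (i, j), g in np.ndenumerate(gw):
                up, dn = tiny_net(
                    net.input_weights, net.neuron_offsets, net.output_weights,
                    net.output_offset,
                ), tiny_net(
                    net.input_weights, net.neuron_offsets, net.output_weights,
                    net.output_offset,
                )
                up.input_weights = net.input_weights.copy()
                dn.input_weights = net.input_weights.copy()
                up.input_weights[i, j] += eps
                dn.input_weights[i, j] -= eps
                fd = (loss(up) - loss(dn)) / (2 * eps)
                assert g == pytest.approx(fd, rel=1e-5, abs=1e-8)
            fd_b = (
                loss(tiny_net(net.input_weights, net.neuron_offsets,
                              net.output_weights, net.output_offset + eps))
                - loss(tiny_net(net.input_weights, net.neuron_offsets,
                                net.output_weights, net.output_offset - eps))
            ) / (2 * eps)
            assert gb == pytest.approx(fd_b, rel=1e-5, abs=1e-8)


class TestTraining:
    @pytest.fixture()
    def separable(self):
        ds = simulate_features(SimSpec(n=120, difficulty=6.0, seed=5), dims=2)
        return ds.subset(np.arange(0, 80)), ds.subset(np.arange(80, 120))

    def test_determinism(self, separable):
        train, verify = separable
        cfg = TrainConfig(n_neurons=2, max_iters=60)
        a = train_network(train, verify, cfg, seed=9)
        b = train_network(train, verify, cfg, seed=9)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert a.net_threshold == b.net_threshold

    def test_separable_data_reaches_perfect_J(self, separable):
        train, verify = separable
        cfg = TrainConfig(n_neurons=2, max_iters=300, learning_rate=0.5)
        net = train_network(train, verify, cfg, seed=2)
        scores = network_forward(train.features, net)
        _, j = youden_threshold(scores, train.labels)
        assert j == pytest.approx(1.0)

    def test_single_class_rejected(self):
        bad = Dataset(np.zeros((4, 1)), [0, 0, 0, 0])
        ok = Dataset(np.zeros((4, 1)), [0, 1, 0, 1])
        with pytest.raises(ValueError):
            train_network(bad, ok, TrainConfig(), seed=0)


@pytest.fixture(scope="module")
def ensemble_and_pool():
    pool = simulate_features(SimSpec(n=150, difficulty=5.0, seed=21), dims=3)
    cfg = TrainConfig(n_candidates=12, n_keep=5, n_neurons=2, max_iters=80, seed=77)
    return train_ensemble(pool, cfg), pool, cfg


class TestEnsembleTraining:
    def test_keeps_exactly_n_keep(self, ensemble_and_pool):
        ens, _, cfg = ensemble_and_pool
        assert ens.K == cfg.n_keep
        assert all(0 < net.net_threshold < 1 for net in ens.networks)
        assert ens.vote_threshold == 2.5

    def test_reproducible(self, ensemble_and_pool):
        ens, pool, cfg = ensemble_and_pool
        again = train_ensemble(pool, cfg)
        for a, b in zip(ens.networks, again.networks):
            assert np.array_equal(a.input_weights, b.input_weights)
            assert a.net_threshold == b.net_threshold
        assert again.ensemble_threshold == ens.ensemble_threshold

    def test_high_pool_accuracy_on_separable_data(self, ensemble_and_pool):
        from betavote import EnsembleUncertaintyModel

        ens, pool, _ = ensemble_and_pool
        res = EnsembleUncertaintyModel.from_ensemble(ens, pool).fit()
        assert res.stats.sensitivity >= 0.95
        assert res.stats.specificity >= 0.95


class TestInputGradientRanking:
    def test_zero_network_keeps_input_order(self):
        net = tiny_net(np.zeros((3, 1)), [0.0], [0.0], 0.0)
        ds = Dataset(np.eye(3), [0, 1, 0])
        assert input_gradient_ranking(net, ds).tolist() == [0, 1, 2]

    def test_dominant_weight_ranks_first(self, rng):
        # single neuron: |dg/dx_i| proportional to |w_i|
        net = tiny_net(np.array([[2.0], [0.1]]), [0.0], [1.0], 0.0)
        ds = Dataset(rng.uniform(-1, 1, (20, 2)), rng.integers(0, 2, 20))
        assert input_gradient_ranking(net, ds)[0] == 0

    def test_matches_finite_difference_gradient(self, rng):
        net = tiny_net(rng.uniform(-1, 1, (3, 2)), rng.uniform(-1, 1, 2),
                       rng.uniform(-1, 1, 2), 0.3)
        X = rng.uniform(-1, 1, (10, 3))
        ds = Dataset(X, rng.integers(0, 2, 10))
        eps = 1e-5
        fd = np.zeros(3)
        for i in range(3):
            Xp, Xm = X.copy(), X.copy()
            Xp[:, i] += eps
            Xm[:, i] -= eps
            fd[i] = np.mean(
                np.abs(network_forward(Xp, net) - network_forward(Xm, net)) / (2 * eps)
            )
        ranked = input_gradient_ranking(net, ds)
        assert ranked.tolist() == np.argsort(-fd, kind="stable").tolist()


class TestDescriptorFilter:
    def test_cuts_applied(self, rng):
        n = 50
        good = rng.normal(0, 1, (n, 2))
        low_cv = np.full((n, 1), 10.0) + rng.normal(0, 0.0001, (n, 1))
        sparse = np.zeros((n, 1))
        sparse[:2, 0] = 1.0
        dup = good[:, :1] * 1.0001
        X = np.hstack([good, low_cv, sparse, dup])
        kept = filter_descriptors(X)
        assert 0 in kept and 1 in kept
        assert 2 not in kept  # coefficient of variation < 1%
        assert 3 not in kept  # nonzero in fewer than 4 cases
        assert 4 not in kept  # |r| > 0.98 with column 0
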