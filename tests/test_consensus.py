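"""Vote tallies, thresholds, confusion statistics and count profiles."""

import numpy as np
import pytest

from betavote import (
    VoteMatrix,
    classify,
    confusion_stats,
    continuity_correct,
    count_profiles,
    naive_vote_threshold,
    tally_votes,
    youden_threshold,
)
from betavote.consensus import CountProfile, uncorrect


def brute_force_youden(scores, labels):
    """Oracle: evaluate J at every midpoint and both guards directly."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    distinct = np.unique(scores)
    cands = np.concatenate(
        ([distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1])
    )
    best_t, best_j = None, -np.inf
    for t in cands:
        pred = scores > t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        if sens + spec - 1 > best_j + 1e-12:
            best_t, best_j = t, sens + spec - 1
    return best_t, best_j


class TestYouden:
    def test_perfect_separation(self):
        t, j = youden_threshold([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.45)
        assert j == 1.0

    def test_tied_maximizers_take_lowest(self):
        t, j = youden_threshold([0.1, 0.6, 0.4, 0.9], [0, 0, 1, 1])
        assert j == pytest.approx(0.5)
        assert t == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.5, 0.9], [0, 0, 0])

    def test_matches_bruteforce_oracle(self, rng):
        # the vectorized scan must agree with direct evaluation of J
        for _ in range(200):
            n = rng.integers(4, 25)
            scores = rng.uniform(size=n).round(2)  # force ties sometimes
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            t, j = youden_threshold(scores, labels)
            bt, bj = brute_force_youden(scores, labels)
            assert j == pytest.approx(bj, abs=1e-12)
            # same classification at both thresholds, not merely same J
            assert np.array_equal(scores > t, scores > bt)

    def test_guard_cuts_reachable(self):
        # anti-correlated scores: no midpoint beats J=0, attained at the
        # guards; the lowest guard (everything positive) wins the tie
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        t, j = youden_threshold(scores, [0, 0, 1, 1])
        assert j == pytest.approx(0.0)
        assert (scores > t).all()


class TestConfusionStats:
    def test_counted_example(self):
        # TP=8 FN=2 TN=9 FP=1
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        pred = np.r_[np.ones(8, int), np.zeros(2, int), np.ones(1, int), np.zeros(9, int)]
        s = confusion_stats(pred, labels)
        assert s.sensitivity == pytest.approx(0.8)
        assert s.specificity == pytest.approx(0.9)
        assert s.J == pytest.approx(0.7)
        assert s.MR == pytest.approx(0.15)
        assert s.PPV == pytest.approx(0.8889, abs=1e-4)
        assert s.NPV == pytest.approx(0.8182, abs=1e-4)

    def test_perfect_prediction(self):
        labels = np.array([0, 1, 0, 1, 1])
        s = confusion_stats(labels, labels)
        assert (s.sensitivity, s.specificity, s.J, s.MR) == (1.0, 1.0, 1.0, 0.0)

    def test_J_identity_random_tables(self, rng):
        for _ in range(100):
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pred = rng.integers(0, 2, 50)
            s = confusion_stats(pred, labels)
            assert s.J == s.sensitivity + s.specificity - 1.0

    def test_no_positive_predictions_gives_nan_ppv(self):
        s = confusion_stats([0, 0, 0, 0], [0, 1, 0, 1])
        assert np.isnan(s.PPV)
        assert s.NPV == pytest.approx(0.5)


class TestTallyAndClassify:
    def test_direct_tally(self):
        vm = VoteMatrix(outputs=[[0.2, 0.6, 0.9]], labels=[1])
        t = tally_votes(vm, "voting", net_thresholds=[0.5, 0.5, 0.5])
        assert t.tolist() == [2]

    def test_all_zero_outputs(self):
        vm = VoteMatrix(outputs=np.zeros((5, 4)), labels=[0, 1, 0, 1, 0])
        t = tally_votes(vm, "voting", net_thresholds=np.full(4, 0.5))
        assert t.tolist() == [0] * 5

    def test_averaging_equals_voting_at_shared_threshold(self, small_vote_matrix):
        vm = small_vote_matrix
        tv = tally_votes(vm, "voting", net_thresholds=np.full(vm.K, 0.5))
        ta = tally_votes(vm, "averaging", ensemble_threshold=0.5)
        assert np.array_equal(tv, ta)

    def test_majority_rule_is_strict(self):
        vm = VoteMatrix(outputs=np.full((2, 33), 0.0), labels=[0, 0])
        assert naive_vote_threshold(33) == 16.5
        assert classify(vm, "voting", tallies=[17, 16], vote_threshold=16.5).tolist() == [1, 0]

    def test_integer_vote_threshold_rejected(self):
        vm = VoteMatrix(outputs=np.zeros((1, 3)), labels=[0])
        with pytest.raises(ValueError):
            classify(vm, "voting", tallies=[2], vote_threshold=2)

    def test_unanimous_negative_consistent_under_averaging(self):
        # all outputs below theta => tally 0 and negative classification
        vm = VoteMatrix(outputs=np.full((4, 5), 0.2), labels=[0, 1, 0, 1])
        t = tally_votes(vm, "averaging", ensemble_threshold=0.5)
        c = classify(vm, "averaging", ensemble_threshold=0.5)
        assert t.tolist() == [0] * 4 and c.tolist() == [0] * 4

    def test_threshold_count_mismatch(self, small_vote_matrix):
        with pytest.raises(ValueError):
            tally_votes(small_vote_matrix, "voting", net_thresholds=[0.5])


class TestCountProfiles:
    def test_empty_input(self):
        p = count_profiles([], [], K=3)
        assert p.pred_counts.tolist() == [0, 0, 0, 0]
        assert p.err_counts.tolist() == [0, 0, 0, 0]

    def test_direct_count(self):
        p = count_profiles([0, 0, 3], [True, False, True], K=3)
        assert p.pred_counts.tolist() == [2, 0, 0, 1]
        assert p.err_counts.tolist() == [1, 0, 0, 0]

    def test_conservation(self, small_vote_matrix, rng):
        vm = small_vote_matrix
        t = tally_votes(vm, "voting", net_thresholds=np.full(vm.K, 0.5))
        correct = rng.integers(0, 2, vm.n).astype(bool)
        p = count_profiles(t, correct, vm.K)
        assert p.pred_counts.sum() == vm.n
        assert p.err_counts.sum() == (~correct).sum()
        assert np.all(p.err_counts <= p.pred_counts)

    def test_out_of_range_tally(self):
        with pytest.raises(ValueError):
            count_profiles([4], [True], K=3)


class TestContinuityCorrection:
    def test_corrected_rates(self):
        raw = CountProfile(
            K=2,
            pred_counts=np.array([0.0, 1.0, 1.0]),
            err_counts=np.array([0.0, 0.0, 1.0]),
        )
        corr = continuity_correct(raw)
        rates = corr.contingent_rates
        assert rates[0] == 0.5  # empty bin
        assert rates[1] == 0.25  # single correct prediction
        assert rates[2] == 0.75  # single incorrect prediction

    def test_double_correction_rejected(self):
        raw = count_profiles([0, 1], [True, True], K=1)
        with pytest.raises(ValueError):
            continuity_correct(continuity_correct(raw))

    def test_round_trip(self):
        raw = count_profiles([0, 1, 1, 0], [True, False, True, True], K=2)
        back = uncorrect(continuity_correct(raw))
        assert np.array_equal(back.pred_counts, raw.pred_counts)
        assert np.array_equal(back.err_counts, raw.err_counts)
        assert not back.corrected
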