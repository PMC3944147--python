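"""Phred transform, features, network training, calibration."""

import numpy as np
import pytest

from hashalign.mapq import (AlignmentFeatures, MapqNetwork,
                            calibration_curve, label_correctness,
                            phred_from_prob, predict_mapq, read_entropy,
                            train_network)


class TestPhred:
    @pytest.mark.parametrize("p,q", [(0.001, 30), (1.0, 0), (0.1, 10)])
    def test_examples(self, p, q):
        assert phred_from_prob(p) == q

    def test_floor_clips_to_qmax(self):
        assert phred_from_prob(1e-9) == 60
        assert phred_from_prob(0) == 60

    def test_over_one_rejected(self):
        with pytest.raises(ValueError):
            phred_from_prob(1.5)

    def test_roundtrip_integer_scores(self):
        for q in range(0, 61):
            assert phred_from_prob(10 ** (-q / 10)) == q


class TestEntropy:
    def test_known_values(self):
        assert read_entropy("AAAA") == 0
        assert read_entropy("ACGTACGT") == 2
        assert read_entropy("AACG") == pytest.approx(1.5)


class TestLabelCorrectness:
    def test_window_edges(self):
        args = ("chr1", "+", "chr1", 1000, "+")
        assert label_correctness("chr1", 1000, "+", "chr1", 1000, "+")
        assert label_correctness("chr1", 1020, "+", "chr1", 1000, "+")
        assert not label_correctness("chr1", 1021, "+", "chr1", 1000, "+")

    def test_wrong_strand_or_ref_incorrect(self):
        assert not label_correctness("chr1", 1000, "-", "chr1", 1000, "+")
        assert not label_correctness("chr2", 1000, "+", "chr1", 1000, "+")

    def test_missing_truth_raises(self):
        with pytest.raises(ValueError):
            label_correctness("chr1", 0, "+", None, 0, "+")


def separable_features(rng, n=4000):
    """Wrong alignments have tiny score gaps; correct ones big gaps."""
    y = (rng.random(n) < 0.5).astype(int)
    best = np.full(n, 0.98)
    second = np.where(y == 1, best - 0.001, best - 0.3)
    X = np.column_stack([
        best, second, np.full(n, 1.9), rng.integers(1, 5, n),
        rng.integers(20, 60, n), np.zeros(n)])
    return X, y


class TestTrainNetwork:
    def test_separable_features_learned(self, rng):
        X, y = separable_features(rng)
        net, report = train_network(X, y, seed=0)
        assert report["holdout_accuracy"] >= 0.99

    def test_label_permutation_is_uninformative(self, rng):
        X, y = separable_features(rng)
        yp = rng.permutation(y)
        net, report = train_network(X, yp, seed=0)
        prior = report["class_prior"]
        baseline = prior * (1 - prior)
        assert report["holdout_brier"] == pytest.approx(baseline, rel=0.25)

    def test_single_class_rejected(self, rng):
        X, _ = separable_features(rng, 200)
        with pytest.raises(ValueError, match="single class"):
            train_network(X, np.zeros(200, int), seed=0)

    def test_training_deterministic_given_seed(self, rng):
        X, y = separable_features(rng, 1000)
        n1, _ = train_network(X, y, seed=7)
        n2, _ = train_network(X, y, seed=7)
        probe = X[:50]
        np.testing.assert_array_equal(n1.predict_q(probe),
                                      n2.predict_q(probe))


class TestPredict:
    def test_untrained_network_errors(self):
        net = MapqNetwork()
        with pytest.raises(RuntimeError):
            net.predict_prob(np.zeros((1, 6)))

    def test_exact_tie_forced_to_zero(self, rng):
        X, y = separable_features(rng)
        net, _ = train_network(X, y, seed=0)
        tied = AlignmentFeatures(0.98, 0.98, 1.9, 2, 40, 0.0)
        assert predict_mapq(net, tied) == 0

    def test_tie_exempt_keeps_network_quality(self, rng):
        X, y = separable_features(rng)
        net, _ = train_network(X, y, seed=0)
        row = AlignmentFeatures(0.98, 0.98, 1.9, 2, 40, 0.0).as_array()
        q = net.predict_q(row[None, :], tie_exempt=np.array([True]))
        assert q[0] >= 0   # override bypassed; network value used
        q0 = net.predict_q(row[None, :])
        assert q0[0] == 0

    def test_larger_gap_never_lowers_quality(self, rng):
        """Monotonicity probe over the score-gap axis."""
        X, y = separable_features(rng)
        net, _ = train_network(X, y, seed=0)
        gaps = np.linspace(0.0, 0.3, 16)
        rows = np.column_stack([
            np.full(16, 0.98), 0.98 - gaps, np.full(16, 1.9),
            np.full(16, 2), np.full(16, 40), np.zeros(16)])
        q = net.predict_q(rows)
        assert np.all(np.diff(q[1:]) >= 0)  # beyond the tie override

    def test_qmax_via_probability_floor(self, rng):
        X, y = separable_features(rng)
        net, _ = train_network(X, y, seed=0)
        assert net.predict_q(X[:200]).max() <= 60


class TestCalibrationCurve:
    def _toy(self, qs, wrong_fracs, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        assigned, correct = [], []
        for q, w in zip(qs, wrong_fracs):
            assigned += [q] * n
            correct += list(rng.random(n) >= w)
        return np.array(assigned), np.array(correct)

    def test_well_calibrated_bins_high_r(self):
        aq, ok = self._toy([10, 20, 30], [0.1, 0.01, 0.001], n=20_000)
        table, r = calibration_curve(aq, ok)
        assert r > 0.99
        assert np.all(np.abs(table.assigned_q - table.actual_q) <= 2)

    def test_anti_calibrated_negative_r(self):
        aq, ok = self._toy([5, 15, 25, 35, 45],
                           [0.001, 0.005, 0.02, 0.1, 0.4], n=5000)
        _, r = calibration_curve(aq, ok)
        assert r < 0

    def test_constant_assignment_errors(self):
        aq, ok = self._toy([20], [0.01])
        with pytest.raises(ValueError):
            calibration_curve(aq, ok)

    def test_sparse_bins_dropped(self):
        rng = np.random.default_rng(3)
        aq = np.concatenate([np.full(2000, 10), np.full(2000, 20),
                             np.full(2000, 30), np.full(5, 40)])
        ok = np.concatenate([rng.random(2000) >= 0.1,
                             rng.random(2000) >= 0.01,
                             rng.random(2000) >= 0.001,
                             np.ones(5, bool)])
        table, _ = calibration_curve(aq, ok, min_bin=30)
        assert 40 not in set(table.assigned_q)
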