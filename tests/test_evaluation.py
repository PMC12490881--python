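"""Classifier, error metrics, correlation/t-test statistics, IOI, features."""

import numpy as np
import pytest

from semgdec.evaluation import (
    AnatomicalRanges,
    classification_report,
    fit_classifier,
    ioi_analysis,
    majority_vote_by_event,
    mean_absolute_error_deg,
    normalized_joint_error,
    paired_t_test,
    setting_correlation,
    signal_features,
    central_frequency_variance,
)
from semgdec.session_io import JOINT_NAMES


def _clusters(n_classes=14, per_class=40, spread=0.5, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 90, (n_classes, 16))
    X, y = [], []
    for i in range(n_classes):
        X.append(centers[i] + rng.normal(0, spread, (per_class, 16)))
        y += [f"g{i:02d}"] * per_class
    return np.vstack(X), np.array(y)


class TestClassifier:
    def test_separable_clusters_classified_perfectly(self):
        X, y = _clusters()
        idx = np.arange(len(y))
        rng = np.random.default_rng(1)
        rng.shuffle(idx)
        tr, te = idx[:400], idx[400:]
        clf = fit_classifier(X[tr], y[tr], seed=0)
        assert (clf.predict(X[te]) == y[te]).mean() == 1.0

    def test_shuffled_labels_score_at_chance(self):
        X, y = _clusters(per_class=80)
        rng = np.random.default_rng(2)
        y_shuf = rng.permutation(y)
        tr = np.arange(0, len(y), 2)
        te = np.arange(1, len(y), 2)
        clf = fit_classifier(X[tr], y_shuf[tr], seed=0)
        acc = (clf.predict(X[te]) == y_shuf[te]).mean()
        # 95% binomial interval around 1/14 with n = 560
        p, n = 1 / 14, len(te)
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(acc - p) < half + 0.02

    def test_single_class_flagged_and_constant(self):
        X = np.zeros((10, 16))
        with pytest.warns(RuntimeWarning, match="single class"):
            clf = fit_classifier(X, np.array(["only"] * 10), seed=0)
        assert (clf.predict(np.ones((5, 16))) == "only").all()

    def test_majority_vote_aggregation(self):
        preds = np.array(["a", "a", "b", "b", "b", "c"])
        events = np.array([0, 0, 0, 1, 1, -1])
        votes = majority_vote_by_event(preds, events)
        assert votes == {0: "a", 1: "b"}  # tie in event 0 -> lexicographic


class TestNormalizedError:
    def test_perfect_prediction_is_zero(self):
        x = np.random.default_rng(0).uniform(0, 90, (5, 16))
        assert np.all(normalized_joint_error(x, x) == 0)

    def test_error_equal_to_range_is_one(self):
        ranges = AnatomicalRanges({j: 45.0 for j in JOINT_NAMES})
        pred = np.full((1, 16), 45.0)
        truth = np.zeros((1, 16))
        assert np.allclose(normalized_joint_error(pred, truth, ranges), 1.0)

    def test_nine_degrees_on_ninety_range_is_point_one(self):
        ranges = AnatomicalRanges({j: 90.0 for j in JOINT_NAMES})
        pred = np.full((1, 16), 9.0)
        truth = np.zeros((1, 16))
        assert np.allclose(normalized_joint_error(pred, truth, ranges), 0.1)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AnatomicalRanges({j: 0.0 for j in JOINT_NAMES})

    def test_mae_in_degrees(self):
        pred = np.array([[3.0] * 16])
        truth = np.array([[1.0] * 16])
        assert mean_absolute_error_deg(pred, truth) == pytest.approx(2.0)


class TestClassificationReport:
    def test_perfect_predictions(self):
        vocab = [f"g{i}" for i in range(14)]
        y = np.repeat(vocab, 3)
        rep = classification_report(y, y, vocab)
        assert rep.accuracy == 1.0
        assert np.trace(rep.confusion) == len(y)
        assert all(v == 1.0 for v in rep.f1_per_class.values())

    def test_constant_predictor_on_balanced_truths(self):
        vocab = [f"g{i}" for i in range(14)]
        truths = np.repeat(vocab, 5)
        preds = np.full_like(truths, "g0")
        rep = classification_report(preds, truths, vocab)
        assert rep.accuracy == pytest.approx(1 / 14)

    def test_three_class_f1_matches_hand_computation(self):
        vocab = ["a", "b", "c"]
        truths = np.array(["a", "a", "a", "b", "b", "c", "c", "c", "c"])
        preds = np.array(["a", "a", "b", "b", "c", "c", "c", "a", "c"])
        rep = classification_report(preds, truths, vocab)
        # a: tp=2 fp=1 fn=1 -> F1 = 2*2/(4+1+1) = 2/3
        # b: tp=1 fp=1 fn=1 -> F1 = 2/4 = 1/2
        # c: tp=3 fp=1 fn=1 -> F1 = 6/8 = 3/4
        assert rep.f1_per_class["a"] == pytest.approx(2 / 3)
        assert rep.f1_per_class["b"] == pytest.approx(1 / 2)
        assert rep.f1_per_class["c"] == pytest.approx(3 / 4)
        assert rep.accuracy == pytest.approx(6 / 9)
        # invariants: rows sum to per-class truth counts; trace/total = acc
        assert rep.confusion.sum(axis=1).tolist() == [3, 2, 4]

    def test_label_outside_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classification_report(np.array(["x"]), np.array(["a"]), ["a", "b"])


class TestSettingCorrelation:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.3, 0.9, 8)
        acc = np.column_stack([a, a, rng.uniform(0.3, 0.9, 8)])
        r = setting_correlation(acc)
        assert r[0, 1] == pytest.approx(1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_negated_column_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.3, 0.9, 8)
        acc = np.column_stack([a, 2 * a.mean() - a])
        r = setting_correlation(acc)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        acc = rng.uniform(0, 1, (10000, 2))
        r = setting_correlation(acc)
        assert abs(r[0, 1]) < 0.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        acc = rng.uniform(0.2, 0.8, (12, 4))
        r1 = setting_correlation(acc)
        r2 = setting_correlation(acc * 3.0 + 0.5)
        assert np.allclose(r1, r2, atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            setting_correlation(np.zeros((2, 4)))


class TestPairedTTest:
    def test_identical_vectors(self):
        a = np.array([0.5, 0.6, 0.7, 0.8])
        res = paired_t_test(a, a.copy())
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        a = np.array([0.5, 0.6, 0.7])
        res = paired_t_test(a + 0.1, a)
        assert res.degenerate
        assert res.p == 0.0
        assert np.isinf(res.t) and res.t > 0

    def test_matches_scipy_on_generic_data(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        a = rng.normal(0.6, 0.1, 16)
        b = rng.normal(0.55, 0.1, 16)
        res = paired_t_test(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t_test(np.zeros(3), np.zeros(4))


class TestIoi:
    def test_perfect_metronome(self):
        onsets = np.arange(10) * 8.0
        res = ioi_analysis(onsets)
        assert res.mean_abs_deviation == 0.0
        assert np.all(res.cdf_x == 8.0)

    def test_alternating_seven_nine(self):
        onsets = np.cumsum([0, 7, 9, 7, 9, 7, 9])
        res = ioi_analysis(onsets)
        assert res.mean_abs_deviation == pytest.approx(1.0)

    def test_jitterless_protocol_has_zero_deviation(self, small_annotation, small_protocol):
        res = ioi_analysis(
            small_annotation.onsets(), ideal_cycle=small_protocol.cycle
        )
        assert res.mean_abs_deviation == pytest.approx(0.0, abs=1e-9)

    def test_single_onset_rejected(self):
        with pytest.raises(ValueError, match="2 onsets"):
            ioi_analysis(np.array([1.0]))


class TestSignalFeatures:
    def test_constant_signal_has_no_crossings(self):
        f = signal_features(np.full(100, 3.3), fs=1000.0)
        assert f.zero_crossings == 0
        assert f.slope_sign_changes == 0

    def test_ten_hertz_sine_crossings(self):
        fs = 1000.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 10 * t + 0.4)  # phase avoids on-grid zeros
        f = signal_features(x, fs, dead_band=0.0)
        assert f.zero_crossings == 20

    def test_counts_match_bruteforce_on_random_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.standard_normal(300)
            db = 0.01
            f = signal_features(x, fs=1000.0, dead_band=db)

            def brute(sig):
                s = [v for v in sig if abs(v) > db]
                return sum(
                    1 for a, b in zip(s, s[1:]) if (a > 0) != (b > 0)
                )

            assert f.zero_crossings == brute(x)
            assert f.slope_sign_changes == brute(np.diff(x))

    def test_pure_tone_centroid_within_a_bin(self):
        fs = 2000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 137.0 * t)
        f = signal_features(x, fs)
        assert abs(f.central_frequency - 137.0) <= fs / len(x) + 1e-9

    def test_identical_windows_zero_centroid_variance(self):
        rng = np.random.default_rng(6)
        w = rng.standard_normal(512)
        assert central_frequency_variance(np.tile(w, (5, 1)), fs=4000.0) == 0.0

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            signal_features(np.array([1.0]), fs=1000.0)
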