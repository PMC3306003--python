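"""Nucleotide-level evaluation: confusion counts, Sn/Sp/AC, ROC/AUC, threshold rule."""

import numpy as np
import pytest
from scipy import stats

from exonscan.metrics import (
    ConfusionCounts,
    approximate_correlation,
    call_exons,
    confusion_at_threshold,
    confusion_from_arrays,
    fp_at_sensitivity_arrays,
    roc_from_arrays,
    sensitivity,
    specificity,
    train_threshold,
)
from exonscan.types import ExonAnnotation, ScoreTrack


def brute_force_confusion(scores, labels, t):
    tp = tn = fp = fn = 0
    for s, l in zip(scores, labels):
        pred = s >= t
        if pred and l:
            tp += 1
        elif pred and not l:
            fp += 1
        elif not pred and l:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def auc_rank_statistic(scores, labels):
    """Mann-Whitney AUC: fraction of (exon, intron) pairs ranked correctly, ties 1/2."""
    labels = np.asarray(labels, dtype=bool)
    ranks = stats.rankdata(scores)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusion:
    def test_perfect_split(self):
        track = ScoreTrack("s", np.array([9.0, 9.0, 1.0, 1.0]))
        truth = ExonAnnotation("s", [(1, 2)])
        c = confusion_at_threshold(track, truth, 5.0)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_zero_threshold_calls_everything(self):
        track = ScoreTrack("s", np.array([9.0, 9.0, 1.0, 1.0]))
        truth = ExonAnnotation("s", [(1, 2)])
        c = confusion_at_threshold(track, truth, 0.0)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 0, 2, 0)

    def test_matches_brute_force_loop(self, rng):
        for _ in range(100):
            scores = rng.integers(0, 10, size=200).astype(float)
            labels = rng.random(200) < 0.3
            t = float(rng.integers(0, 10))
            c = confusion_from_arrays(scores, labels, t)
            assert (c.TP, c.TN, c.FP, c.FN) == brute_force_confusion(scores, labels, t)

    def test_sequence_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_at_threshold(
                ScoreTrack("a", np.ones(4)), ExonAnnotation("b", [(1, 2)]), 0.5
            )

    def test_counts_partition_positions(self, rng):
        scores = rng.random(500)
        labels = rng.random(500) < 0.5
        c = confusion_from_arrays(scores, labels, 0.5)
        assert c.total == 500


class TestSnSpAc:
    def test_sensitivity_formula(self):
        assert sensitivity(ConfusionCounts(TP=80, TN=0, FP=0, FN=20)) == 0.80

    def test_specificity_formula(self):
        assert specificity(ConfusionCounts(TP=80, TN=0, FP=20, FN=0)) == 0.80

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert sensitivity(ConfusionCounts(TP=0, TN=5, FP=5, FN=0)) == 0.0

    def test_perfect_prediction_gives_ac_one(self):
        r = approximate_correlation(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert r.acp == 1.0
        assert r.ac == 1.0

    def test_truth_independent_prediction_gives_ac_zero(self):
        r = approximate_correlation(ConfusionCounts(TP=25, TN=25, FP=25, FN=25))
        assert r.acp == 0.5
        assert r.ac == 0.0

    def test_undefined_terms_are_omitted_from_the_mean(self):
        # TN+FN = 0 makes TN/(TN+FN) undefined; the three remaining terms are
        # TP/(TP+FN) = 1, TP/(TP+FP) = 0.5 and TN/(TN+FP) = 0 (defined: its
        # denominator is 50), so ACP = 0.5 and AC = 0.
        r = approximate_correlation(ConfusionCounts(TP=50, TN=0, FP=50, FN=0))
        assert r.acp == pytest.approx(0.5)
        assert r.ac == pytest.approx(0.0)

    def test_all_terms_undefined_rejected(self):
        with pytest.raises(ValueError):
            approximate_correlation(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_ac_is_affine_in_acp(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
            r = approximate_correlation(ConfusionCounts(tp, tn, fp, fn))
            assert r.ac == pytest.approx((r.acp - 0.5) * 2, abs=1e-15)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([True, True, False, False])
        assert roc_from_arrays(scores, labels).auc == 1.0

    def test_identical_scores_give_chance(self):
        scores = np.ones(10)
        labels = np.arange(10) < 4
        assert roc_from_arrays(scores, labels).auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_ordering_fraction(self, rng):
        for _ in range(50):
            scores = rng.integers(0, 6, size=20).astype(float)
            labels = rng.random(20) < 0.5
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            expected = np.mean(pairs)
            assert roc_from_arrays(scores, labels).auc == pytest.approx(expected, abs=1e-9)

    def test_auc_matches_rank_statistic(self, rng):
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.4
        got = roc_from_arrays(scores, labels).auc
        assert got == pytest.approx(auc_rank_statistic(scores, labels), abs=1e-9)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=400)
        labels = rng.random(400) < 0.3
        got = roc_from_arrays(scores, labels).auc
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.integers(0, 20, 300).astype(float)
        labels = rng.random(300) < 0.5
        curve = roc_from_arrays(scores, labels)
        assert curve.thresholds[0] == np.inf
        assert np.all(np.diff(curve.thresholds) < 0)
        assert (curve.tpr[0], curve.fpr[0]) == (0.0, 0.0)
        assert (curve.tpr[-1], curve.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_from_arrays(np.ones(5), np.ones(5, dtype=bool))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300) ** 2
        labels = rng.random(300) < 0.4
        base = roc_from_arrays(scores, labels).auc
        assert roc_from_arrays(np.log1p(scores) * 3 + 2, labels).auc == pytest.approx(base, abs=1e-12)

    def test_raising_threshold_never_increases_tp_or_fp(self, rng):
        scores = rng.random(200)
        labels = rng.random(200) < 0.5
        thresholds = np.sort(rng.random(20))
        prev_tp = prev_fp = np.inf
        for t in thresholds:
            c = confusion_from_arrays(scores, labels, t)
            assert c.TP <= prev_tp and c.FP <= prev_fp
            prev_tp, prev_fp = c.TP, c.FP


class TestFpAtSensitivity:
    def test_perfect_separation_has_no_false_positives(self):
        scores = np.concatenate([np.full(10, 5.0), np.zeros(10)])
        labels = np.arange(20) < 10
        fp, sp, ac = fp_at_sensitivity_arrays(scores, labels, 0.5)
        assert fp == 0
        assert sp == 1.0

    def test_flat_scores_call_everything(self):
        scores = np.ones(20)
        labels = np.arange(20) < 5
        fp, sp, ac = fp_at_sensitivity_arrays(scores, labels, 0.2)
        assert fp == 15

    def test_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(30):
            scores = rng.integers(0, 8, 100).astype(float)
            labels = rng.random(100) < 0.4
            if labels.all() or not labels.any():
                continue
            target = 0.6
            best = None
            for t in np.unique(scores)[::-1]:
                c = confusion_from_arrays(scores, labels, t)
                if c.TP / (c.TP + c.FN) >= target:
                    best = t
                    break
            fp, _, _ = fp_at_sensitivity_arrays(scores, labels, target)
            c = confusion_from_arrays(scores, labels, best)
            assert fp == c.FP

    def test_unreachable_target_rejected(self):
        scores = np.zeros(10)
        labels = np.arange(10) < 5
        with pytest.raises(ValueError):
            fp_at_sensitivity_arrays(scores, labels, 1.5)


class TestTrainThreshold:
    def test_equal_spreads_give_midpoint(self):
        model = train_threshold([99.0, 100.0, 101.0], [19.0, 20.0, 21.0])
        assert model.threshold == pytest.approx((100.0 + 20.0) / 2)

    def test_hand_computed_value(self):
        """T = (sd_e*mean_i + sd_i*mean_e)/(sd_e+sd_i) on fixed statistics."""
        from exonscan.metrics import ThresholdModel

        mean_e, sd_e, mean_i, sd_i = 100.0, 10.0, 20.0, 5.0
        t = (sd_e * mean_i + sd_i * mean_e) / (sd_e + sd_i)
        assert t == pytest.approx(46.666666666666664)
        # and via the estimator on samples engineered to those statistics
        exon = [90.0, 100.0, 110.0]  # mean 100, sd 10
        intron = [15.0, 20.0, 25.0]  # mean 20, sd 5
        model = train_threshold(exon, intron)
        assert model.threshold == pytest.approx(t)
        assert isinstance(model, ThresholdModel)

    def test_equal_means_collapse_to_that_mean(self):
        model = train_threshold([9.0, 10.0, 11.0], [8.0, 10.0, 12.0])
        assert model.threshold == pytest.approx(10.0)

    def test_threshold_lies_between_label_means(self, rng):
        exon = rng.normal(50, 5, 100)
        intron = rng.normal(10, 3, 100)
        model = train_threshold(exon, intron)
        assert model.mean_intron < model.threshold < model.mean_exon

    def test_trained_threshold_beats_chance_on_separated_data(self, rng):
        """When label means differ by > 1 pooled sd, T gives Sn and 1-FPR above 0.5."""
        exon = rng.normal(30, 4, 500)
        intron = rng.normal(10, 4, 500)
        model = train_threshold(exon, intron)
        scores = np.concatenate([exon, intron])
        labels = np.arange(1000) < 500
        c = confusion_from_arrays(scores, labels, model.threshold)
        assert c.TP / (c.TP + c.FN) > 0.5
        assert c.TN / (c.TN + c.FP) > 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_threshold([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            train_threshold([5.0, 5.0], [3.0, 3.0])


class TestCallExons:
    def test_single_run(self):
        track = ScoreTrack("s", np.array([0.0, 5.0, 5.0, 0.0]))
        ann = call_exons(track, 3.0, min_length=1, merge_gap=0)
        assert ann.intervals == [(2, 3)]

    def test_gap_bridging(self):
        track = ScoreTrack("s", np.array([5.0, 0.0, 5.0]))
        ann = call_exons(track, 3.0, merge_gap=1)
        assert ann.intervals == [(1, 3)]

    def test_minimum_length_filter(self):
        track = ScoreTrack("s", np.array([0.0, 5.0, 5.0, 0.0]))
        ann = call_exons(track, 3.0, min_length=3)
        assert ann.intervals == []
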