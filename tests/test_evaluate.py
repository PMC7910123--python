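"""Evaluation stack vs brute-force counting / pairwise oracles."""

import numpy as np
import pytest

from rnnlr.evaluate import (ConfusionMatrix, confusion, evaluation_report,
                            one_vs_all_metrics, paired_t, pr_curve,
                            repeated_trials, roc_auc_ova, round2,
                            worked_example_confusion)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 2, 2]))

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion(np.array([], dtype=int), np.array([], dtype=int))
        assert cm.counts.sum() == 0

    def test_string_labels_accepted(self):
        cm = confusion(["neither", "AHE"], ["HRS", "AHE"])
        assert cm.counts[0, 2] == 1 and cm.counts[1, 1] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="sepsis"):
            confusion(["sepsis"], ["AHE"])

    def test_published_matrix_row_sums(self):
        cm = worked_example_confusion()
        assert cm.row_sums().tolist() == [1262, 12, 35]
        assert cm.n == 1309


class TestOneVsAll:
    def test_published_matrix_ahe_metrics(self):
        cm = worked_example_confusion()
        p, r, f = one_vs_all_metrics(cm, "AHE")
        assert p == pytest.approx(5 / 24)
        assert r == pytest.approx(5 / 12)
        assert (round2(p), round2(r), round2(f)) == (0.21, 0.42, 0.28)

    def test_published_matrix_hrs_metrics(self):
        cm = worked_example_confusion()
        p, r, f = one_vs_all_metrics(cm, "HRS")
        assert r == pytest.approx(14 / 35)
        assert p == pytest.approx(14 / 179)
        assert (round2(p), round2(r), round2(f)) == (0.08, 0.40, 0.13)

    def test_against_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.integers(0, 3, 30)
            yhat = rng.integers(0, 3, 30)
            cm = confusion(y, yhat)
            for k in range(3):
                tp = int(np.sum((y == k) & (yhat == k)))
                fp = int(np.sum((y != k) & (yhat == k)))
                fn = int(np.sum((y == k) & (yhat != k)))
                p, r, f = one_vs_all_metrics(cm, k)
                assert p == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
                assert r == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)

    def test_zero_division_convention(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [1, 0, 0], [1, 0, 0]]))
        with pytest.warns(UserWarning, match="undefined"):
            p, r, f = one_vs_all_metrics(cm, 1)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_micro_consistency(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.integers(0, 3, 50), rng.integers(0, 3, 50)
        cm = confusion(y, yhat)
        tps = [cm.counts[k, k] for k in range(3)]
        assert sum(tps) == np.trace(cm.counts)


def _pairs_auc(y, scores):
    """O(n^2) all-pairs oracle, ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1, 0], [0.8, 0.2, 0],
                          [0.3, 0.7, 0], [0.1, 0.9, 0]])
        assert roc_auc_ova(y, probs, 1) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 2000)
        probs = np.zeros((2000, 3))
        probs[:, 1] = rng.random(2000)
        assert abs(roc_auc_ova(y, probs, 1) - 0.5) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        y = rng.integers(0, 2, n)
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        probs = np.zeros((n, 3))
        probs[:, 1] = scores
        assert roc_auc_ova(y, probs, 1) == pytest.approx(
            _pairs_auc(y, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        probs = np.zeros((300, 3))
        probs[:, 1] = s
        a = roc_auc_ova(y, probs, 1)
        probs[:, 1] = np.exp(3 * s)  # strictly monotone
        assert roc_auc_ova(y, probs, 1) == pytest.approx(a)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ova(np.ones(5, dtype=int), np.ones((5, 3)) / 3, 1)


class TestPrCurve:
    def test_perfect_scores_reach_top_corner(self):
        y = np.array([0, 0, 1, 1])
        probs = np.zeros((4, 3))
        probs[:, 1] = [0.1, 0.2, 0.8, 0.9]
        pts = pr_curve(y, probs, 1)
        assert (1.0, 1.0) in pts

    def test_all_positive_threshold_hits_prevalence(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        probs = np.zeros((200, 3))
        probs[:, 1] = rng.random(200)
        pts = pr_curve(y, probs, 1)
        recalls = [r for r, _ in pts]
        i = int(np.argmax(recalls))
        assert recalls[i] == 1.0
        assert pts[i][1] == pytest.approx(y.mean())

    def test_points_match_per_threshold_recomputation(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 60)
        s = np.round(rng.random(60), 1)
        probs = np.zeros((60, 3))
        probs[:, 1] = s
        pts = dict()
        for r, p in pr_curve(y, probs, 1):
            pts.setdefault(round(r, 12), set()).add(round(p, 12))
        for thr in np.unique(s):
            pred = s >= thr
            tp = int(np.sum(pred & (y == 1)))
            rec = tp / (y == 1).sum()
            prec = tp / pred.sum()
            assert round(prec, 12) in pts[round(rec, 12)]


class TestRepeatedTrials:
    def test_trials_table_has_one_row_per_seed(self):
        df = repeated_trials(lambda s: {"auc": s / 10}, seeds=range(5))
        assert df.shape[0] == 5
        assert df.auc.tolist() == [0.0, 0.1, 0.2, 0.3, 0.4]

    def test_identical_vectors_mean_difference_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_constant_shift_triggers_degenerate_branch(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_t(a + 1.0, a)
        assert p == 0.0

    def test_statistic_matches_hand_formula(self):
        a = np.array([0.80, 0.82, 0.78, 0.85, 0.81])
        b = np.array([0.75, 0.80, 0.77, 0.80, 0.78])
        t, p = paired_t(a, b)
        d = a - b
        hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(hand)
        assert 0 < p < 1


def test_report_renders_published_rows_exactly():
    cm = worked_example_confusion()
    rows = {}
    for i, label in enumerate(cm.class_order):
        p, r, f = one_vs_all_metrics(cm, i)
        rows[label] = (round2(p), round2(r), round2(f))
    assert rows["neither"] == (0.98, 0.85, 0.91)
    assert rows["AHE"] == (0.21, 0.42, 0.28)
    assert rows["HRS"] == (0.08, 0.40, 0.13)
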