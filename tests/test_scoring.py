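"""ROC/AUROC, cutoff optimization, weighted score and the panel."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from atacscore.scoring import (OpennessPanel, TargetPanel,
                               classification_metrics, find_cutoff,
                               roc_auroc, weighted_score)


def pair_count_auroc(scores, labels):
    r = [s for s, l in zip(scores, labels) if l]
    n = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in r:
        for b in n:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(r) * len(n))


def corner_distance(scores, threshold, labels):
    m = classification_metrics(scores, threshold, labels)
    return math.hypot(1 - m.sensitivity, 1 - m.specificity)


class TestAuroc:
    def test_perfect_separation(self):
        assert roc_auroc([5, 6, 1, 2], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auroc([3, 3, 3, 3], [True, True, False, False]) == 0.5

    def test_interleaved_example(self):
        assert roc_auroc([1, 3, 2, 4], [True, True, False, False]) == 0.25

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auroc([1, 2], [True, True])

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 11, size=2)
            scores = rng.integers(0, 6, size=n1 + n2).astype(float)
            labels = np.array([True] * n1 + [False] * n2)
            assert roc_auroc(scores, labels) == pair_count_auroc(scores, labels)

    def test_agrees_with_sklearn_trapezoid(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.integers(0, 8, size=16).astype(float)
            labels = rng.random(16) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestFindCutoff:
    def test_separable_gives_perfect_metrics(self):
        scores = [10, 11, 1, 2]
        labels = [True, True, False, False]
        t = find_cutoff(scores, labels)
        assert 2 < t < 10
        m = classification_metrics(scores, t, labels)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_degenerate_all_equal_warns_and_predicts_nonresponder(self):
        with pytest.warns(UserWarning, match="identical"):
            t = find_cutoff([5, 5, 5], [True, False, True])
        m = classification_metrics([5, 5, 5], t, [True, False, True])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_globally_optimal_over_candidate_grid(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=50).round(2)
        labels = rng.random(50) < 0.4
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        t = find_cutoff(scores, labels)
        uniq = np.unique(scores)
        candidates = np.concatenate(
            [[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]]
        )
        best = min(corner_distance(scores, c, labels) for c in candidates)
        assert corner_distance(scores, t, labels) == pytest.approx(best, abs=1e-12)

    def test_metrics_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        grid = np.sort(scores)
        sens = [classification_metrics(scores, t, labels).sensitivity for t in grid]
        spec = [classification_metrics(scores, t, labels).specificity for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestClassificationMetrics:
    def test_threshold_above_all_scores(self):
        m = classification_metrics([1, 2, 3], 10, [True, False, True])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        t = float(rng.normal())
        m = classification_metrics(scores, t, labels)
        tp = sum(1 for s, l in zip(scores, labels) if l and s > t)
        fn = sum(1 for s, l in zip(scores, labels) if l and s <= t)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s <= t)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s > t)
        assert (m.tp, m.fn, m.tn, m.fp) == (tp, fn, tn, fp)
        assert m.accuracy == (tp + tn) / 40


class TestWeightedScore:
    def test_all_above_gives_45_none_gives_0(self):
        w = list(range(1, 10))
        assert weighted_score([1] * 9, w) == 45
        assert weighted_score([0] * 9, w) == 0

    def test_only_top_rank_target(self):
        weights = [9, 8, 7, 6, 5, 4, 3, 2, 1]
        bits = [1, 0, 0, 0, 0, 0, 0, 0, 0]
        assert weighted_score(bits, weights) == 9

    def test_brute_force_over_all_vectors(self):
        rng = np.random.default_rng(5)
        weights = list(rng.permutation(np.arange(1, 10)))
        extremes = []
        for bits in itertools.product([0, 1], repeat=9):
            s = weighted_score(bits, weights)
            assert s == sum(b * w for b, w in zip(bits, weights))
            if s in (0, 45):
                extremes.append(bits)
        assert extremes == [tuple([0] * 9), tuple([1] * 9)]

    def test_monotone_in_bits(self):
        weights = list(range(9, 0, -1))
        bits = [0, 1, 0, 1, 0, 1, 0, 1, 0]
        base = weighted_score(bits, weights)
        for i in range(9):
            if bits[i] == 0:
                flipped = list(bits)
                flipped[i] = 1
                assert weighted_score(flipped, weights) >= base

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_score([1, 0], [1, 2, 3])


class TestOpennessPanel:
    def test_weights_are_9_down_to_1_by_accuracy(self, discovery_result):
        panel = discovery_result["panel"].panel_
        assert panel.weights == list(range(9, 0, -1))
        assert panel.accuracies == sorted(panel.accuracies, reverse=True)

    def test_apply_on_training_reproduces_fit_scores(self, discovery_result):
        est = discovery_result["panel"]
        matrix = discovery_result["normalized"]["k20"]
        rebuilt = OpennessPanel.from_panel(est.panel_)
        eval_samples = list(est.train_scores_.index)
        scores = rebuilt.decision_function(matrix, samples=eval_samples)
        np.testing.assert_array_equal(scores, est.train_scores_.to_numpy())

    def test_panel_json_round_trip_scores_identical(self, discovery_result,
                                                    tmp_path):
        est = discovery_result["panel"]
        matrix = discovery_result["normalized"]["k20"]
        path = tmp_path / "panel.json"
        est.panel_.to_json(path)
        reloaded = OpennessPanel.from_panel(TargetPanel.from_json(path))
        np.testing.assert_array_equal(
            reloaded.decision_function(matrix), est.decision_function(matrix)
        )

    def test_missing_target_peak_listed_in_error(self, discovery_result):
        est = discovery_result["panel"]
        matrix = discovery_result["normalized"]["k20"]
        victim = est.panel_.target_ids[0]
        keep = [p.peak_id for p in matrix.peaks if p.peak_id != victim]
        with pytest.raises(ValueError, match=victim):
            est.decision_function(matrix.subset_peaks(keep))

    def test_wrong_target_count_rejected(self, discovery_result):
        matrix = discovery_result["normalized"]["k20"]
        labels = discovery_result["sheet"].set_index("sample_id")["response"].to_dict()
        bad = OpennessPanel(targets=[p.peak_id for p in matrix.peaks[:5]])
        with pytest.raises(ValueError, match="9"):
            bad.fit(matrix, labels)
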