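"""PR-curve evaluation against brute-force oracles, and rank comparison."""

import numpy as np
import pandas as pd
import pytest

import hmclmlp as hm
from hmclmlp import published
from hmclmlp.evaluation import significance_matrix
from conftest import random_scores_truth


def naive_pr_counts(scores, truth, hierarchy, threshold, scope=None):
    """Double-loop TP/FP/FN counter over explicitly decoded predictions."""
    pred = hm.decode(scores, hierarchy, threshold).labels
    cols = range(hierarchy.class_count) if scope is None else scope
    TP = FP = FN = 0
    for i in range(pred.shape[0]):
        for j in cols:
            p, t = bool(pred[i, j]), bool(truth[i, j])
            TP += p and t
            FP += p and not t
            FN += (not p) and t
    return TP, FP, FN


def step_function_area(scores, truth, hierarchy, n_thresholds=10_001):
    """Fine-grid threshold sweep, no interpolation beyond the step function."""
    repaired = hierarchy.min_path_scores(np.atleast_2d(scores))
    s = repaired.ravel()
    t = np.atleast_2d(truth).ravel().astype(bool)
    pos = t.sum()
    area = 0.0
    prev_rec = 0.0
    for thr in np.linspace(1.0, 0.0, n_thresholds):
        p = s >= thr
        tp = np.sum(p & t)
        fp = np.sum(p & ~t)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / pos
        area += (rec - prev_rec) * prec
        prev_rec = rec
    return area


class TestPRPoint:
    def test_perfect_scores_give_perfect_point(self, tiny_hierarchy):
        truth = tiny_hierarchy.labels_to_matrix([{"12.01"}, {"20"}])
        scores = truth.astype(float)
        pt = hm.pr_point(scores, truth, tiny_hierarchy, 0.5)
        assert pt.precision == 1.0 and pt.recall == 1.0

    def test_manual_count_example(self):
        # 2 flat classes, 3 instances; predictions fixed by the threshold
        h = hm.build_hierarchy([("1",), ("2",)])
        truth = np.array([[1, 0], [0, 1], [1, 1]])
        scores = np.array([[0.9, 0.8], [0.1, 0.7], [0.2, 0.6]])
        pt = hm.pr_point(scores, truth, h, 0.5)
        assert (pt.TP, pt.FP, pt.FN) == (3, 1, 1)
        assert pt.precision == 0.75 and pt.recall == 0.75

    def test_threshold_zero_has_full_recall(self, tiny_hierarchy):
        rng = np.random.default_rng(3)
        scores, truth = random_scores_truth(tiny_hierarchy, 10, rng)
        pt = hm.pr_point(scores, truth, tiny_hierarchy, 0.0)
        assert pt.recall == 1.0

    def test_counts_equal_naive_counter_exactly(self, small_synth):
        h = small_synth.hierarchy
        rng = np.random.default_rng(11)
        scores, truth = random_scores_truth(h, 12, rng)
        for thr in (0.0, 0.3, 0.55, 0.9, 1.0):
            pt = hm.pr_point(scores, truth, h, thr)
            assert (pt.TP, pt.FP, pt.FN) == naive_pr_counts(
                scores, truth, h, thr
            )


class TestPRCurve:
    def test_perfect_ranking_gives_area_one(self):
        h = hm.build_hierarchy([("1",)])
        truth = np.array([[1], [1], [0], [0]])
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        assert hm.pr_curve(scores, truth, h).area == pytest.approx(1.0)

    def test_recalls_nondecreasing_and_area_in_unit_interval(self, small_synth):
        h = small_synth.hierarchy
        rng = np.random.default_rng(5)
        scores, truth = random_scores_truth(h, 25, rng)
        curve = hm.pr_curve(scores, truth, h)
        recalls = [p.recall for p in curve.points]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))
        assert 0.0 <= curve.area <= 1.0

    def test_identical_scores_area_equals_prevalence(self, tiny_hierarchy):
        rng = np.random.default_rng(8)
        _, truth = random_scores_truth(tiny_hierarchy, 12, rng)
        scores = np.full(truth.shape, 0.7)
        curve = hm.pr_curve(scores, truth, tiny_hierarchy)
        assert curve.area == pytest.approx(truth.mean())
        achievable = [p for p in curve.points if p.TP > 0]
        assert len(achievable) == 1
        assert achievable[0].recall == 1.0

    def test_step_mode_matches_fine_grid_oracle(self, small_synth):
        """The no-interpolation area rule reproduces a brute-force
        10,001-threshold sweep (grid discretization error only)."""
        h = small_synth.hierarchy
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(5, 41))
            scores, truth = random_scores_truth(h, n, rng)
            mine = hm.au_prc_micro(scores, truth, h, method="step")
            oracle = step_function_area(scores, truth, h)
            assert mine == pytest.approx(oracle, abs=1e-3)

    def test_interpolated_equals_step_without_score_ties(self):
        """On a flat hierarchy with all-distinct scores every achievable
        point differs by one sample, so interpolation adds nothing and the
        two area rules coincide."""
        h = hm.build_hierarchy([("1",), ("2",), ("3",)])
        rng = np.random.default_rng(31)
        scores, truth = random_scores_truth(h, 30, rng)
        if truth.sum() == 0:
            truth[0, 0] = 1
        a = hm.au_prc_micro(scores, truth, h)
        b = hm.au_prc_micro(scores, truth, h, method="step")
        assert a == pytest.approx(b, abs=1e-12)

    def test_instance_permutation_invariance(self, small_synth):
        h = small_synth.hierarchy
        rng = np.random.default_rng(23)
        scores, truth = random_scores_truth(h, 20, rng)
        perm = rng.permutation(20)
        assert hm.au_prc_micro(scores, truth, h) == pytest.approx(
            hm.au_prc_micro(scores[perm], truth[perm], h)
        )

    def test_no_positives_in_scope_rejected(self, tiny_hierarchy):
        scores = np.random.default_rng(0).random((4, 4))
        truth = np.zeros((4, 4), dtype=np.int8)
        with pytest.raises(ValueError):
            hm.pr_curve(scores, truth, tiny_hierarchy)

    def test_per_level_scope_equals_pooled_curve_on_level(self, small_synth):
        h = small_synth.hierarchy
        rng = np.random.default_rng(29)
        scores, truth = random_scores_truth(h, 30, rng)
        rep = hm.evaluate_model(scores, truth, h)
        for l in range(1, h.max_depth + 1):
            expected = hm.au_prc_micro(scores, truth, h, h.levels[l])
            assert rep.per_level[l] == pytest.approx(expected)


class TestWeightedAverages:
    def test_frequency_weighting_example(self):
        areas = {"a": 0.5, "b": 1.0}
        w = hm.ClassWeights({"a": 0.25, "b": 0.75}, "frequency")
        assert hm.auprc_weighted(areas, w) == pytest.approx(0.875)

    def test_uniform_mode_is_arithmetic_mean(self):
        areas = {"a": 0.2, "b": 0.4}
        w = hm.ClassWeights.uniform(["a", "b"])
        assert hm.auprc_weighted(areas, w) == pytest.approx(0.3)

    def test_single_class_returns_its_area(self):
        w = hm.ClassWeights.uniform(["a"])
        assert hm.auprc_weighted({"a": 0.42}, w) == pytest.approx(0.42)

    def test_key_mismatch_rejected(self):
        w = hm.ClassWeights.uniform(["a", "b"])
        with pytest.raises(ValueError):
            hm.auprc_weighted({"a": 0.5}, w)

    def test_frequency_weights_sum_to_one(self, small_synth):
        h = small_synth.hierarchy
        Y = small_synth.train.label_matrix()
        w = hm.ClassWeights.frequency(Y, h, h.class_ids)
        assert sum(w.weights.values()) == pytest.approx(1.0)


class TestEvaluateModel:
    def test_perfect_scores_all_metrics_one(self, tiny_hierarchy):
        truth = tiny_hierarchy.labels_to_matrix(
            [{"12.01.01"}, {"20"}, {"12"}]
        )
        rep = hm.evaluate_model(truth.astype(float), truth, tiny_hierarchy)
        assert rep.au_prc_micro == pytest.approx(1.0)
        assert rep.auprc_weighted == pytest.approx(1.0)
        assert rep.auprc_uniform == pytest.approx(1.0)
        assert rep.excluded_classes == []

    def test_positive_free_classes_are_excluded_and_listed(self, tiny_hierarchy):
        truth = tiny_hierarchy.labels_to_matrix([{"12"}, {"20"}])
        scores = np.random.default_rng(1).random(truth.shape)
        rep = hm.evaluate_model(scores, truth, tiny_hierarchy)
        assert set(rep.excluded_classes) == {"12.01", "12.01.01"}
        assert set(rep.per_class) == {"12", "20"}


class TestAverageRanks:
    def test_reproduces_published_micro_ranks(self):
        ranks = hm.average_ranks(published.AU_PRC_MICRO)
        assert ranks["Predicted"] == pytest.approx(1.35)
        assert ranks["Clus-HMC"] == pytest.approx(3.55)
        assert ranks["Labels"] == pytest.approx(4.90)

    def test_reproduces_all_published_rank_cells(self):
        expected = {
            "au_prc_micro": {"Labels": 4.90, "Predicted": 1.35, "True": 3.40,
                             "NoLabels": 2.50, "Clus-HMC": 3.55,
                             "Clus-HSC": 7.20, "Clus-SC": 7.80,
                             "hmAnt-Miner": 5.30},
            "auprc_weighted": {"Labels": 6.65, "Predicted": 1.25,
                               "True": 3.45, "NoLabels": 2.75,
                               "Clus-HMC": 3.85, "Clus-HSC": 5.70,
                               "Clus-SC": 5.55, "hmAnt-Miner": 6.80},
            "auprc_uniform": {"Labels": 8.00, "Predicted": 4.10,
                              "True": 6.15, "NoLabels": 5.45,
                              "Clus-HMC": 2.20, "Clus-HSC": 1.90,
                              "Clus-SC": 2.70, "hmAnt-Miner": 5.50},
        }
        for measure, table in published.TABLES.items():
            ranks = hm.average_ranks(table)
            for method, value in expected[measure].items():
                assert ranks[method] == pytest.approx(value), (measure, method)

    def test_full_ties_share_average_rank(self):
        table = pd.DataFrame({"A": [0.5, 0.6], "B": [0.5, 0.6]})
        ranks = hm.average_ranks(table)
        assert ranks["A"] == ranks["B"] == 1.5

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            hm.average_ranks(pd.DataFrame({"A": [0.1, np.nan], "B": [0.2, 0.3]}))


class TestNemenyi:
    def test_eight_methods_ten_datasets(self):
        # q_0.05(k=8)/sqrt(2) = 3.031; CD = 3.031 * sqrt(8*9/60)
        assert hm.nemenyi_cd(8, 10, 0.05) == pytest.approx(3.320, abs=0.005)

    def test_two_methods_reduce_to_normal_quantile(self):
        cd = hm.nemenyi_cd(2, 10, 0.05)
        assert cd == pytest.approx(1.960 * np.sqrt(6 / 60), abs=1e-3)

    def test_zero_gap_never_significant(self):
        ranks = pd.Series({"A": 2.0, "B": 2.0, "C": 5.0})
        sig = significance_matrix(ranks, n_datasets=10)
        assert not sig.loc["A", "B"]

    def test_unsupported_alpha(self):
        with pytest.raises(ValueError):
            hm.nemenyi_cd(5, 10, alpha=0.01)


class TestPerClassWins:
    def _grids(self):
        idx = [f"d{i}" for i in range(10)]
        a = pd.DataFrame(0.5, index=idx, columns=["c1", "c2", "c3"])
        b = a.copy()
        a.loc[:, "c1"] += 0.1            # A wins c1 on 10/10
        b.loc["d0":"d8", "c2"] += 0.1    # B wins c2 on 9/10
        return a, b

    def test_nine_of_ten_threshold(self):
        a, b = self._grids()
        best, worst = hm.per_class_wins(a, b, min_wins=9)
        assert best == ["c1"] and worst == ["c2"]

    def test_ties_count_for_neither(self):
        idx = ["d0", "d1"]
        a = pd.DataFrame(0.5, index=idx, columns=["c"])
        best, worst = hm.per_class_wins(a, a.copy(), min_wins=1)
        assert best == [] and worst == []

    def test_sixty_percent_mode(self):
        a, b = self._grids()
        b2 = b.copy()
        b2.loc["d0":"d5", "c3"] += 0.1   # B wins c3 on 6/10
        best, worst = hm.per_class_wins(a, b2, min_wins=6)
        assert best == ["c1"] and set(worst) == {"c2", "c3"}

    def test_misaligned_grids_rejected(self):
        a, b = self._grids()
        with pytest.raises(ValueError):
            hm.per_class_wins(a, b.iloc[:, :2], min_wins=9)
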