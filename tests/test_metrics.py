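"""Instance matching, detection/classification metrics, parent-class bounds,
DQ+ and the Friedman test, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import friedman_no_ties_oracle, optimal_one_to_one, random_blob_fixture
from phenogate import (
    ClassMapping,
    ConfigurationError,
    InstanceMap,
    MappingError,
    MatchResult,
    bounded_metrics,
    classification_metrics,
    confusion_matrix,
    detection_metrics,
    dq_plus,
    friedman_test,
    match_instances,
    prevalence_normalized_ppv,
)
from phenogate.image import DimensionError


def map_of(array):
    return InstanceMap(np.asarray(array, dtype=np.int32))


class TestMatching:
    def test_identity_maps_match_perfectly(self, rng):
        labels = rng.integers(0, 5, size=(32, 32)).astype(np.int32)
        m = match_instances(map_of(labels), map_of(labels))
        assert not m.unmatched_pred and not m.unmatched_gt
        assert all(iou == 1.0 for *_, iou in m.pairs)

    def test_one_pred_two_gts_takes_higher_iou(self):
        # gt 1 occupies cols 0..9, gt 2 cols 12..21 on 2 rows; pred 1 overlaps
        # gt1 on 6 cols and gt2 on 3 cols
        gt = np.zeros((2, 24), dtype=np.int32)
        gt[:, 0:10] = 1
        gt[:, 12:22] = 2
        pred = np.zeros((2, 24), dtype=np.int32)
        pred[:, 4:15] = 1
        m = match_instances(map_of(pred), map_of(gt), 0.1)
        assert len(m.pairs) == 1
        assert m.pairs[0][0] == 1 and m.pairs[0][1] == 1
        assert m.unmatched_gt == [2]

    def test_iou_exactly_at_threshold_not_matched(self):
        # pred covers 1 px inside a 4-px gt: IoU = 1/4 exactly
        gt = np.zeros((4, 4), dtype=np.int32)
        gt[0:2, 0:2] = 1
        pred = np.zeros((4, 4), dtype=np.int32)
        pred[0, 0] = 1
        m = match_instances(map_of(pred), map_of(gt), 0.25)
        assert m.pairs == []
        assert m.unmatched_pred == [1] and m.unmatched_gt == [1]
        # epsilon below the threshold it does match
        m2 = match_instances(map_of(pred), map_of(gt), 0.25 - 1e-9)
        assert len(m2.pairs) == 1

    def test_greedy_equals_exhaustive_optimal_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            pred, gt = random_blob_fixture(rng)
            greedy = match_instances(pred, gt, 0.25)
            optimal = optimal_one_to_one(pred, gt, 0.25)
            assert sorted((p, g) for p, g, _ in greedy.pairs) == sorted(
                (p, g) for p, g, _ in optimal
            )

    def test_threshold_monotonicity_and_cardinality(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pred, gt = random_blob_fixture(rng)
            sizes = []
            for thr in (0.1, 0.25, 0.4, 0.6, 0.8):
                m = match_instances(pred, gt, thr)
                sizes.append(len(m.pairs))
                assert len(m.pairs) <= min(pred.n_instances, gt.n_instances)
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            match_instances(map_of(np.zeros((4, 4))), map_of(np.zeros((5, 5))))


class TestDetectionMetrics:
    def test_perfect(self):
        m = MatchResult([(1, 1, 1.0), (2, 2, 1.0)], [], [])
        d = detection_metrics(m)
        assert d == {"precision": 1.0, "recall": 1.0, "f1": 1.0, "mean_iou_tp": 1.0}

    def test_hand_arithmetic(self):
        m = MatchResult([(1, 1, 0.5), (2, 2, 0.7), (3, 3, 0.9)], [4], [4, 5])
        d = detection_metrics(m)
        assert d["precision"] == pytest.approx(0.75)
        assert d["recall"] == pytest.approx(0.6)
        assert d["f1"] == pytest.approx(2 / (1 / 0.75 + 1 / 0.6))
        assert d["mean_iou_tp"] == pytest.approx(0.7)

    def test_degenerate_zero_predictions_warns(self):
        m = MatchResult([], [], [1, 2])
        with pytest.warns(UserWarning):
            d = detection_metrics(m)
        assert d["precision"] == 0.0 and d["recall"] == 0.0


class TestClassificationMetrics:
    def test_all_correct(self):
        pairs = pd.DataFrame({"pred_class": ["a", "b", "a"], "gt_class": ["a", "b", "a"]})
        out = classification_metrics(pairs)
        assert (out["ppv"].dropna() == 1.0).all()
        assert (out["npv"].dropna() == 1.0).all()

    def test_hand_tallied_toy(self):
        #            pred:  a  a  a  b  b  c  c  c  c  a
        #            gt:    a  a  b  b  b  c  a  c  c  c
        pairs = pd.DataFrame(
            {
                "pred_class": list("aaabbcccca"),
                "gt_class": list("aabbbcaccc"),
            }
        )
        out = classification_metrics(pairs, class_names=["a", "b", "c"])
        # class a: TP=2, FP=2, FN=1, TN=5
        assert out.loc["a", "ppv"] == pytest.approx(2 / 4)
        assert out.loc["a", "npv"] == pytest.approx(5 / 6)
        assert out.loc["a", "prevalence"] == pytest.approx(3 / 10)
        assert out.loc["a", "accuracy"] == pytest.approx(7 / 10)
        # class b: TP=2, FP=0, FN=1, TN=7
        assert out.loc["b", "ppv"] == pytest.approx(1.0)
        assert out.loc["b", "npv"] == pytest.approx(7 / 8)
        # class c: TP=3, FP=1, FN=1, TN=5
        assert out.loc["c", "ppv"] == pytest.approx(3 / 4)
        assert out.loc["c", "prevalence"] == pytest.approx(4 / 10)

    def test_absent_class_definitions(self):
        pairs = pd.DataFrame({"pred_class": ["a", "a"], "gt_class": ["a", "a"]})
        out = classification_metrics(pairs, class_names=["a", "z"])
        assert out.loc["z", "prevalence"] == 0.0
        assert out.loc["z", "npv"] == 1.0  # denominator = all instances

    def test_confusion_marginals_equal_counts(self, rng):
        classes = ["a", "b", "c", "d"]
        pairs = pd.DataFrame(
            {
                "pred_class": rng.choice(classes, 200),
                "gt_class": rng.choice(classes, 200),
            }
        )
        cm = confusion_matrix(pairs, classes)
        assert cm.to_numpy().sum() == 200
        for c in classes:
            assert cm.loc[c].sum() == (pairs["gt_class"] == c).sum()
            assert cm[c].sum() == (pairs["pred_class"] == c).sum()

    def test_unknown_class_rejected(self):
        pairs = pd.DataFrame({"pred_class": ["weird"], "gt_class": ["a"]})
        with pytest.raises(ConfigurationError):
            classification_metrics(pairs, class_names=["a"])


MAPPING = ClassMapping(
    {
        "helper T": "lymphocyte",
        "cytotoxic T": "lymphocyte",
        "enterocyte": "epithelial",
        "progenitor": "epithelial",
    }
)


class TestBoundedMetrics:
    def test_parent_correct_no_siblings(self):
        mapping = ClassMapping({"x": "P", "y": "Q"})
        pairs = pd.DataFrame(
            {
                "pred_class": ["x"] * 4 + ["y"] * 6,
                "gt_parent": ["P"] * 4 + ["Q"] * 6,
            }
        )
        out = bounded_metrics(pairs, mapping)
        assert out.loc["x", "ppv_upper"] == 1.0
        # x's negatives: the 6 y-rows, all with other parents
        assert out.loc["x", "npv_lower"] == 1.0
        assert out.loc["x", "npv_upper"] == 1.0

    def test_twenty_instance_hand_oracle(self):
        rows = (
            [("helper T", "lymphocyte")] * 3 + [("helper T", "epithelial")] * 2
            + [("cytotoxic T", "lymphocyte")] * 2 + [("cytotoxic T", "epithelial")] * 1
            + [("enterocyte", "epithelial")] * 5 + [("enterocyte", "lymphocyte")] * 1
            + [("progenitor", "epithelial")] * 2 + [("progenitor", "lymphocyte")] * 4
        )
        pairs = pd.DataFrame(rows, columns=["pred_class", "gt_parent"])
        out = bounded_metrics(pairs, MAPPING)
        assert out.loc["helper T", "ppv_upper"] == pytest.approx(3 / 5)
        # negatives of helper T: 15 rows; definite TN (gt != lymphocyte) = 8;
        # ambiguous = 7 of which 2 predicted as the sibling cytotoxic T
        assert out.loc["helper T", "npv_lower"] == pytest.approx(8 / 15)
        assert out.loc["helper T", "npv_upper"] == pytest.approx(10 / 15)
        assert out.loc["enterocyte", "ppv_upper"] == pytest.approx(5 / 6)

    def test_unmapped_prediction_raises(self):
        pairs = pd.DataFrame({"pred_class": ["mystery"], "gt_parent": ["P"]})
        with pytest.raises(MappingError):
            bounded_metrics(pairs, MAPPING)

    def test_monte_carlo_bound_sandwich(self):
        """True fine-level PPV <= ppv_upper and npv_lower <= true NPV <= 1,
        and npv_lower <= npv_upper, over random confusion scenarios."""
        rng = np.random.default_rng(11)
        fine = list(MAPPING.parent_of)
        for _ in range(200):
            n = int(rng.integers(20, 80))
            gt_fine = rng.choice(fine, n)
            pred_fine = np.where(rng.random(n) < 0.5, gt_fine, rng.choice(fine, n))
            pairs = pd.DataFrame(
                {
                    "pred_class": pred_fine,
                    "gt_parent": [MAPPING.parent(c) for c in gt_fine],
                }
            )
            bounds = bounded_metrics(pairs, MAPPING, fine_classes=fine)
            for c in fine:
                pred_c = pred_fine == c
                if pred_c.any():
                    true_ppv = np.mean(gt_fine[pred_c] == c)
                    assert true_ppv <= bounds.loc[c, "ppv_upper"] + 1e-12
                neg = ~pred_c
                if neg.any():
                    true_npv = np.mean(gt_fine[neg] != c)
                    assert bounds.loc[c, "npv_lower"] <= true_npv + 1e-12
                    assert bounds.loc[c, "npv_lower"] <= bounds.loc[c, "npv_upper"] + 1e-12


class TestPrevalenceNormalizedPPV:
    def test_ratio_identity_is_chance_level(self):
        assert prevalence_normalized_ppv(0.21, 0.21) == pytest.approx(1.0)

    def test_published_scale_example(self):
        # an upper-bound PPV of 0.43 at parent prevalence 0.21 is ~2x chance
        assert prevalence_normalized_ppv(0.43, 0.21) == pytest.approx(2.0476, abs=1e-3)

    def test_zero_prevalence_is_missing_not_error(self):
        assert np.isnan(prevalence_normalized_ppv(0.5, 0.0))


class TestDQPlus:
    def test_perfect(self):
        m = MatchResult([(1, 1, 1.0), (2, 2, 1.0)], [], [])
        out = dq_plus(m, {1: "a", 2: "b"}, {1: "a", 2: "b"})
        assert out == {"a": 1.0, "b": 1.0}

    def test_counting_oracle(self):
        # class a: TP=2 (pairs 1,2), FP=1 (unmatched pred 3), FN=1 (unmatched gt 9)
        m = MatchResult([(1, 1, 0.9), (2, 2, 0.9)], [3], [9])
        out = dq_plus(m, {1: "a", 2: "a", 3: "a"}, {1: "a", 2: "a", 9: "a"})
        assert out["a"] == pytest.approx(2 / 3)

    def test_empty_class_missing(self):
        m = MatchResult([], [1], [])
        out = dq_plus(m, {1: "a"}, {}, classes=["a", "b"])
        assert out["a"] == 0.0
        assert np.isnan(out["b"])

    def test_parent_mode_dominates_fine_mode(self):
        """Monte-Carlo: the parent-credited DQ+ upper bound never falls below
        the fine-grained DQ+ when parent gt refines fine gt."""
        rng = np.random.default_rng(23)
        fine = list(MAPPING.parent_of)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            ids = list(range(1, n + 1))
            gt_fine = {i: str(rng.choice(fine)) for i in ids}
            pred_fine = {i: str(rng.choice(fine)) for i in ids}
            matched = [i for i in ids if rng.random() < 0.7]
            pairs = [(i, i, 0.9) for i in matched]
            unmatched = [i for i in ids if i not in matched]
            m = MatchResult(pairs, unmatched, unmatched)
            fine_dq = dq_plus(m, pred_fine, gt_fine)
            gt_parent = {i: MAPPING.parent(c) for i, c in gt_fine.items()}
            parent_dq = dq_plus(m, pred_fine, gt_parent, parent_mode=True, mapping=MAPPING)
            for c, v in fine_dq.items():
                if not np.isnan(v):
                    assert parent_dq[c] >= v - 1e-12


class TestFriedman:
    def test_identical_columns(self):
        values = np.tile([3.0, 3.0, 3.0, 3.0], (5, 1))
        stat, p = friedman_test(values)
        assert stat == 0.0 and p == 1.0

    def test_matches_untied_rank_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.random((5, 5))
            stat, p = friedman_test(values)
            assert stat == pytest.approx(friedman_no_ties_oracle(values))
            s_stat, s_p = sps.friedmanchisquare(*values.T)
            assert stat == pytest.approx(s_stat)
            assert p == pytest.approx(s_p)

    def test_column_permutation_invariance(self, rng):
        values = rng.random((6, 4))
        stat, _ = friedman_test(values)
        perm = rng.permutation(4)
        stat_p, _ = friedman_test(values[:, perm])
        assert stat == pytest.approx(stat_p)

    def test_two_treatments_hand_example(self):
        values = np.array([[1.0, 2.0], [1.0, 2.0], [2.0, 1.0]])
        stat, p = friedman_test(values)
        assert stat == pytest.approx(1 / 3)
        assert p == pytest.approx(float(sps.chi2.sf(1 / 3, 1)))

    def test_input_validation(self):
        with pytest.raises(ConfigurationError):
            friedman_test(np.ones((1, 4)))
        with pytest.raises(ConfigurationError):
            friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))
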