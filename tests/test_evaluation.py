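"""Metrics against the standard confusion-matrix formulas, ROC, CV, grid search."""

import math

import numpy as np
import pytest

import recspot as rs
from recspot.errors import DegenerateMetricError, ParameterError
from recspot.evaluation import stratified_folds
from recspot.hybrid import HybridSpec
from recspot.model import DnnConfig
from recspot.pipeline import PipelineSpec


def standard_metrics(tp, tn, fp, fn):
    """TP/TN/FP/FN textbook formulas (independent oracle)."""
    acc = (tp + tn) / (tp + tn + fp + fn)
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return acc, sn, sp, mcc


class TestConfusion:
    def test_all_correct(self):
        c = rs.confusion([0, 0, 1, 1], [0, 0, 1, 1])
        assert (c.pos_as_neg, c.neg_as_pos) == (0, 0)
        assert (c.h_pos, c.h_neg) == (2, 2)

    def test_all_inverted(self):
        c = rs.confusion([0, 0, 1], [1, 1, 0])
        assert c.pos_as_neg == c.h_pos == 2
        assert c.neg_as_pos == c.h_neg == 1

    def test_matches_naive_tally(self, rng):
        t = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        c = rs.confusion(t, p)
        tally = {"pn": 0, "np": 0}
        for ti, pi in zip(t, p):
            if ti == 0 and pi == 1:
                tally["pn"] += 1
            if ti == 1 and pi == 0:
                tally["np"] += 1
        assert (c.pos_as_neg, c.neg_as_pos) == (tally["pn"], tally["np"])

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            rs.confusion([0, 1], [0])


class TestMetrics:
    def test_perfect_predictor(self):
        m = rs.compute_metrics(rs.ConfusionCounts(10, 10, 0, 0))
        assert (m.acc, m.sn, m.sp, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        m = rs.compute_metrics(rs.ConfusionCounts(4, 6, 1, 2))
        assert m.acc == pytest.approx(0.7)
        assert m.sn == pytest.approx(0.75)
        assert m.sp == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(0.4082, abs=1e-4)

    def test_exhaustive_agreement_with_standard_formulas(self):
        """Error-fraction formulation == TP/TN/FP/FN formulas for all tables <= 20."""
        for h_pos in range(1, 21):
            for h_neg in range(1, 21):
                for fn in range(h_pos + 1):
                    for fp in range(h_neg + 1):
                        m = rs.compute_metrics(
                            rs.ConfusionCounts(h_pos, h_neg, fn, fp)
                        )
                        acc, sn, sp, mcc = standard_metrics(
                            h_pos - fn, h_neg - fp, fp, fn
                        )
                        assert m.acc == pytest.approx(acc, abs=1e-12)
                        assert m.sn == pytest.approx(sn, abs=1e-12)
                        assert m.sp == pytest.approx(sp, abs=1e-12)
                        assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_degenerate_class_raises(self):
        with pytest.raises(DegenerateMetricError):
            rs.compute_metrics(rs.ConfusionCounts(0, 10, 0, 3))

    def test_degenerate_mcc_is_zero_not_nan(self):
        # everything predicted coldspot: TP+FP = 0
        m = rs.compute_metrics(rs.ConfusionCounts(5, 5, 5, 0))
        assert m.mcc == 0.0


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        labels = [0, 0, 0, 1, 1]
        roc = rs.roc_auc(scores, labels)
        assert roc.auc == 1.0
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_random_scores_near_half(self, rng):
        labels = rng.integers(0, 2, 2000)
        scores = rng.random(2000)
        assert abs(rs.roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_equals_mann_whitney(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = scores[labels == 0]
            neg = scores[labels == 1]
            u = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert rs.roc_auc(scores, labels).auc == pytest.approx(
                u / (len(pos) * len(neg))
            )

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        a1 = rs.roc_auc(scores, labels).auc
        a2 = rs.roc_auc(np.exp(5 * scores), labels).auc
        assert a1 == pytest.approx(a2)

    def test_fpr_nondecreasing(self, rng):
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        xs = [p[0] for p in rs.roc_auc(scores, labels).points]
        assert all(a <= b for a, b in zip(xs, xs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            rs.roc_auc([0.1, 0.9], [0, 0])


class TestFolds:
    def test_stratification_arithmetic(self):
        y = [0] * 100 + [1] * 100
        folds = stratified_folds(y, k=10, seed=0)
        for _, test_idx in folds:
            arr = np.asarray(y)[test_idx]
            assert (arr == 0).sum() == 10 and (arr == 1).sum() == 10

    def test_folds_partition_samples(self):
        y = [0] * 25 + [1] * 30
        folds = stratified_folds(y, k=5, seed=3)
        seen = np.concatenate([t for _, t in folds])
        assert sorted(seen) == list(range(55))

    def test_seed_reproducibility(self):
        y = [0] * 30 + [1] * 30
        f1 = stratified_folds(y, k=5, seed=4)
        f2 = stratified_folds(y, k=5, seed=4)
        for (_, a), (_, b) in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(ParameterError, match="smaller k"):
            stratified_folds([0] * 3 + [1] * 30, k=10, seed=0)


def _fast_spec(**overrides):
    defaults = dict(
        hybrid=HybridSpec.for_group("G4"),
        classifier=DnnConfig.small(iterations=150, seed=6),
    )
    defaults.update(overrides)
    return PipelineSpec(**defaults)


class TestCrossValidate:
    def test_report_structure_and_reproducibility(self, small_labeled_dataset):
        spec = _fast_spec()
        r1 = rs.cross_validate(small_labeled_dataset, spec, k=4, seed=2)
        r2 = rs.cross_validate(small_labeled_dataset, spec, k=4, seed=2)
        assert len(r1.fold_metrics) == 4
        assert r1.pooled.acc == r2.pooled.acc
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        # pooled confusion equals the sum of per-fold confusions by construction,
        # and covers every sample exactly once
        c = r1.pooled_confusion
        assert c.h_pos + c.h_neg == len(small_labeled_dataset)
        assert (r1.fold_assignment >= 0).all()

    def test_planted_signal_is_learned(self, small_labeled_dataset):
        report = rs.cross_validate(small_labeled_dataset, _fast_spec(), k=4, seed=2)
        assert report.pooled.acc >= 0.9
        assert report.roc.auc >= 0.9

    def test_whole_dataset_selection_mode_runs(self, small_labeled_dataset):
        report = rs.cross_validate(
            small_labeled_dataset,
            _fast_spec(),
            k=4,
            seed=2,
            leakage_mode="whole-dataset-selection",
        )
        assert report.leakage_mode == "whole-dataset-selection"
        assert report.pooled.acc >= 0.9

    def test_unknown_leakage_mode(self, small_labeled_dataset):
        with pytest.raises(ParameterError):
            rs.cross_validate(
                small_labeled_dataset, _fast_spec(), k=4, seed=2, leakage_mode="bogus"
            )


class TestGridSearch:
    def test_single_cell_grid(self, small_labeled_dataset):
        cfg = DnnConfig.small(iterations=100, seed=6)
        res = rs.grid_search(
            small_labeled_dataset, [0.1], ["tanh"], cfg,
            pipeline_spec=_fast_spec(), k=3, seed=1,
        )
        assert res.best_cell == (0.1, "tanh")
        assert set(res.cells) == {(0.1, "tanh")}

    def test_grid_enumerates_all_cells_and_tie_rule(self, small_labeled_dataset):
        cfg = DnnConfig.small(iterations=60, seed=6)
        rates, acts = [0.1, 0.3], ["tanh", "relu"]
        res = rs.grid_search(
            small_labeled_dataset, rates, acts, cfg,
            pipeline_spec=_fast_spec(), k=3, seed=1,
        )
        assert len(res.cells) == 4
        best_acc = max(res.cells.values())
        winners = [c for c, a in res.cells.items() if a == best_acc]
        # tie rule: lowest rate first, then tanh < relu < sigmoid
        expected = min(winners, key=lambda c: (c[0], ["tanh", "relu", "sigmoid"].index(c[1])))
        assert res.best_cell == expected

    def test_empty_grid_rejected(self, small_labeled_dataset):
        with pytest.raises(ParameterError):
            rs.grid_search(
                small_labeled_dataset, [], ["tanh"], DnnConfig.small(),
                pipeline_spec=_fast_spec(),
            )
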