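import math

import numpy as np
import pytest
from oracles import auc_pairwise_oracle, t_statistic_oracle
from scipy import stats

from amni import compute_metrics, paired_t_test, repeated_holdout
from amni.errors import DegenerateStatisticError, ProtocolError
from amni.evaluation import stratified_split
from amni.types import MultimodalSubject, Prediction


def _preds(y, yhat, p1):
    return [
        Prediction(f"s{i}", (1 - p, p), int(h), true_label=int(t))
        for i, (t, h, p) in enumerate(zip(y, yhat, p1))
    ]


class TestMetrics:
    def test_hand_confusion_table(self):
        # TP=3, FN=1, TN=2, FP=2
        y =    [1, 1, 1, 1, 0, 0, 0, 0]
        yhat = [1, 1, 1, 0, 0, 0, 1, 1]
        p1 =   [0.9, 0.8, 0.7, 0.4, 0.2, 0.3, 0.6, 0.55]
        m = compute_metrics(_preds(y, yhat, p1))
        assert m.sen == pytest.approx(0.75)
        assert m.spe == pytest.approx(0.5)
        assert m.acc == pytest.approx(0.625)
        assert m.bac == pytest.approx(0.625)
        assert m.ppv == pytest.approx(0.6)
        assert m.npv == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / (0.6 + 0.75))

    def test_perfect_classifier_scores_one_everywhere(self):
        y = [1, 1, 0, 0]
        m = compute_metrics(_preds(y, y, [0.95, 0.9, 0.1, 0.05]))
        for name in ("acc", "sen", "spe", "bac", "ppv", "npv", "f1", "auc"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_constant_scores_give_half_auc(self):
        y = [1, 0, 1, 0]
        m = compute_metrics(_preds(y, [1, 1, 1, 1], [0.5] * 4))
        assert m.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p1 = np.round(rng.random(n), 2)  # rounding forces ties
            yhat = (p1 > 0.5).astype(int)
            m = compute_metrics(_preds(y, yhat, p1))
            assert m.auc == pytest.approx(auc_pairwise_oracle(y, p1), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        n = 30
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        p1 = rng.random(n)
        yhat = (p1 > 0.5).astype(int)
        base = compute_metrics(_preds(y, yhat, p1)).auc
        for transform in (lambda x: x**3, lambda x: 1 / (1 + np.exp(-5 * x))):
            q = transform(p1)
            q = (q - q.min()) / (q.max() - q.min() + 1e-12)
            m = compute_metrics(_preds(y, yhat, q))
            assert m.auc == pytest.approx(base, abs=1e-12)

    def test_prediction_order_does_not_matter(self, rng):
        y = [1, 0, 1, 0, 1]
        p1 = [0.9, 0.4, 0.6, 0.2, 0.3]
        yhat = [1, 0, 1, 0, 0]
        preds = _preds(y, yhat, p1)
        a = compute_metrics(preds)
        b = compute_metrics(list(reversed(preds)))
        assert a == b

    def test_accuracy_identity(self, rng):
        y = rng.integers(0, 2, size=40)
        p1 = rng.random(40)
        yhat = rng.integers(0, 2, size=40)
        m = compute_metrics(_preds(y, yhat, p1))
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        assert m.acc == pytest.approx(
            (m.sen * n_pos + m.spe * n_neg) / (n_pos + n_neg)
        )

    def test_single_class_truth_marks_undefined_not_zero(self):
        m = compute_metrics(_preds([1, 1, 1], [1, 1, 0], [0.9, 0.8, 0.4]))
        assert "spe" in m.undefined and "auc" in m.undefined
        assert math.isnan(m.spe) and math.isnan(m.auc)
        assert m.sen == pytest.approx(2 / 3)


class _ConstantModel:
    def predict(self, subjects):
        return [
            Prediction(s.subject_id, (0.4, 0.6), 1, true_label=s.label)
            for s in subjects
        ]


def _cohort(n0, n1):
    return [
        MultimodalSubject(f"s{i}", int(i >= n0)) for i in range(n0 + n1)
    ]


class TestRepeatedHoldout:
    def test_split_arithmetic_ten_subjects(self):
        cohort = _cohort(5, 5)
        result = repeated_holdout(
            cohort, lambda subs, seed: _ConstantModel(), n_repeats=1, test_fraction=0.2
        )
        assert len(result.predictions[0]) == 2  # 8 train / 2 test

    def test_same_base_seed_reproduces_splits(self):
        labels = np.array([0] * 10 + [1] * 10)
        a = stratified_split(labels, 0.2, np.random.default_rng(3))
        b = stratified_split(labels, 0.2, np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_splits_are_disjoint_and_stratified(self):
        labels = np.array([0] * 12 + [1] * 8)
        train, test = stratified_split(labels, 0.25, np.random.default_rng(0))
        assert set(train).isdisjoint(test)
        assert len(train) + len(test) == 20
        assert set(labels[test]) == {0, 1}

    def test_summary_statistics_use_sample_std(self):
        calls = iter([0.6, 0.7, 0.8])

        class VaryingModel:
            def __init__(self, acc):
                self.acc = acc

            def predict(self, subjects):
                n = len(subjects)
                correct = int(round(self.acc * n))
                out = []
                for i, s in enumerate(subjects):
                    label = s.label if i < correct else 1 - s.label
                    out.append(
                        Prediction(s.subject_id, (1 - 0.9 * label, 0.9 * label) if label else (0.9, 0.1), label, true_label=s.label)
                    )
                return out

        cohort = _cohort(10, 10)
        result = repeated_holdout(
            cohort,
            lambda subs, seed: VaryingModel(next(calls)),
            n_repeats=3,
            test_fraction=0.5,
        )
        accs = [r.acc for r in result.records]
        assert result.mean["acc"] == pytest.approx(float(np.mean(accs)))
        assert result.std["acc"] == pytest.approx(float(np.std(accs, ddof=1)))

    def test_too_small_cohort_raises_protocol_error(self):
        with pytest.raises(ProtocolError):
            repeated_holdout(
                _cohort(1, 1), lambda subs, seed: _ConstantModel(), n_repeats=1
            )


class TestPairedT:
    def test_hand_evaluated_statistic(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 2 sqrt(3), df = 2
        result = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert result.t_statistic == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert result.n_pairs == 3
        assert result.t_statistic == pytest.approx(
            t_statistic_oracle(np.array([1.0, 2.0, 3.0])), rel=1e-12
        )

    def test_two_sided_p_from_t_distribution(self):
        result = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        expected = 2.0 * stats.t.sf(2 * math.sqrt(3), df=2)
        assert result.p_value == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_reference_implementation(self, rng):
        a = rng.random(25)
        b = rng.random(25)
        ours = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert ours.t_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_swapping_lists_negates_t_keeps_p(self, rng):
        a, b = rng.random(10), rng.random(10)
        fwd = paired_t_test(a, b)
        rev = paired_t_test(b, a)
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_identical_lists_raise_degenerate_error(self):
        with pytest.raises(DegenerateStatisticError):
            paired_t_test([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])

class TestRocPoints:
    def test_roc_endpoints_and_area_consistency(self, rng):
        from oracles import auc_pairwise_oracle

        from amni.evaluation import roc_points

        y = np.r_[np.ones(12, int), np.zeros(12, int)]
        p1 = rng.random(24)
        preds = _preds(y, (p1 > 0.5).astype(int), p1)
        pts = roc_points(preds)
        assert tuple(pts[0][:2]) == (0.0, 0.0)
        assert tuple(pts[-1][:2]) == (1.0, 1.0)
        area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        assert area == pytest.approx(auc_pairwise_oracle(y, p1), abs=1e-12)
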