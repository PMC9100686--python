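import math

import numpy as np
import pytest
from oracles import cross_entropy_oracle, mmd_linear_oracle

from amni import FusionHead, LossConfig, cross_entropy_loss, fuse_and_classify, late_fusion_forward, mmd_loss, total_loss
from amni.errors import ContractViolationError, ParameterError
from amni.fusion import cross_entropy_from_probs, mmd_loss_with_grad
from amni.types import BranchFeature, FeatureBatch, Prediction


def _batch(values, modality="functional"):
    return FeatureBatch(modality=modality, values=np.asarray(values, dtype=float))


class TestMMD:
    def test_identical_batches_give_zero(self, rng):
        x = rng.standard_normal((5, 4))
        for kernel in ("linear", "rbf"):
            cfg = LossConfig(mmd_kernel=kernel)
            assert mmd_loss(_batch(x), _batch(x, "structural"), cfg) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_singleton_batches_linear_kernel_is_distance(self):
        a, b = np.array([[1.0, 2.0]]), np.array([[4.0, 6.0]])
        assert mmd_loss(_batch(a), _batch(b, "structural")) == pytest.approx(5.0)

    def test_matches_mean_then_norm_oracle(self, rng):
        f = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]])
        s = np.array([[2.0, 0.0], [1.0, 1.0], [-1.0, 3.0]])
        got = mmd_loss(_batch(f), _batch(s, "structural"))
        assert got == pytest.approx(mmd_linear_oracle(f, s), rel=1e-12)
        for _ in range(5):
            f = rng.standard_normal((int(rng.integers(1, 9)), 4))
            s = rng.standard_normal((int(rng.integers(1, 9)), 4))
            got = mmd_loss(_batch(f), _batch(s, "structural"))
            assert got == pytest.approx(mmd_linear_oracle(f, s), abs=1e-10)

    def test_symmetry_nonnegativity_and_scaling(self, rng):
        f = rng.standard_normal((6, 3))
        s = rng.standard_normal((4, 3))
        ab = mmd_loss(_batch(f), _batch(s, "structural"))
        ba = mmd_loss(_batch(s), _batch(f, "structural"))
        assert ab == pytest.approx(ba, rel=1e-12)
        assert ab >= 0.0
        scaled = mmd_loss(_batch(-2.5 * f), _batch(-2.5 * s, "structural"))
        assert scaled == pytest.approx(2.5 * ab, rel=1e-10)

    def test_width_mismatch_raises(self, rng):
        with pytest.raises(ContractViolationError):
            mmd_loss(
                _batch(rng.standard_normal((3, 4))),
                _batch(rng.standard_normal((3, 5)), "structural"),
            )

    def test_linear_gradient_matches_finite_differences(self, rng):
        f = rng.standard_normal((4, 3))
        s = rng.standard_normal((5, 3))
        for squared in (False, True):
            cfg = LossConfig(mmd_squared=squared)
            _, df, ds = mmd_loss_with_grad(f, s, cfg)
            eps = 1e-6
            for arr, grad in ((f, df), (s, ds)):
                i = (1, 2)
                orig = arr[i]
                arr[i] = orig + eps
                hi = mmd_loss_with_grad(f, s, cfg)[0]
                arr[i] = orig - eps
                lo = mmd_loss_with_grad(f, s, cfg)[0]
                arr[i] = orig
                assert grad[i] == pytest.approx((hi - lo) / (2 * eps), abs=1e-6)

    def test_squared_option_squares_the_norm(self, rng):
        f, s = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        plain = mmd_loss(_batch(f), _batch(s, "structural"), LossConfig())
        squared = mmd_loss(_batch(f), _batch(s, "structural"), LossConfig(mmd_squared=True))
        assert squared == pytest.approx(plain**2, rel=1e-9)


class TestFusionHead:
    def test_zero_weights_give_uniform_probabilities(self, rng):
        head = FusionHead(8, 4, 2, rng)
        for p in head.params():
            p.value[...] = 0.0
        pred = fuse_and_classify(
            BranchFeature("s1", "functional", rng.standard_normal(4)),
            BranchFeature("s1", "structural", rng.standard_normal(4)),
            head,
        )
        assert pred.probabilities == pytest.approx((0.5, 0.5))

    def test_probabilities_sum_to_one(self, rng):
        head = FusionHead(6, 4, 2, rng)
        pred = fuse_and_classify(
            BranchFeature("s", "functional", rng.standard_normal(3)),
            BranchFeature("s", "structural", rng.standard_normal(3)),
            head,
        )
        assert sum(pred.probabilities) == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_softmax_oracle(self, rng):
        head = FusionHead(2, 2, 2, rng)
        f1 = BranchFeature("s", "functional", [0.5])
        f2 = BranchFeature("s", "structural", [-1.0])
        pred = fuse_and_classify(f1, f2, head)
        x = np.array([0.5, -1.0])
        h = np.maximum(x @ head.fc1.W.value + head.fc1.b.value, 0.0)
        logits = h @ head.fc2.W.value + head.fc2.b.value
        exp = np.exp(logits - logits.max())
        expected = exp / exp.sum()
        assert pred.probabilities == pytest.approx(tuple(expected), rel=1e-12)

    def test_swapping_logits_swaps_probabilities(self, rng):
        head = FusionHead(4, 3, 2, rng)
        f1 = BranchFeature("s", "functional", rng.standard_normal(2))
        f2 = BranchFeature("s", "structural", rng.standard_normal(2))
        pred = fuse_and_classify(f1, f2, head)
        head.fc2.W.value = head.fc2.W.value[:, ::-1].copy()
        head.fc2.b.value = head.fc2.b.value[::-1].copy()
        swapped = fuse_and_classify(f1, f2, head)
        assert swapped.probabilities == pytest.approx(pred.probabilities[::-1])


class TestLosses:
    def test_cross_entropy_closed_forms(self):
        preds = [Prediction("a", (0.5, 0.5), 1, true_label=1)]
        assert cross_entropy_loss(preds) == pytest.approx(math.log(2.0), rel=1e-9)
        perfect = [
            Prediction("a", (0.0, 1.0), 1, true_label=1),
            Prediction("b", (1.0, 0.0), 0, true_label=0),
        ]
        assert cross_entropy_loss(perfect) <= 1e-6

    def test_cross_entropy_matches_two_term_oracle(self):
        preds = [
            Prediction("a", (0.2, 0.8), 1, true_label=1),
            Prediction("b", (0.6, 0.4), 0, true_label=0),
        ]
        expected = cross_entropy_oracle([(1, 0.8), (0, 0.4)])
        assert cross_entropy_loss(preds) == pytest.approx(expected, rel=1e-12)

    def test_cross_entropy_nonnegative_minimized_at_truth(self, rng):
        y = rng.integers(0, 2, size=20)
        p_true = y.astype(float)
        p_other = np.clip(p_true + rng.uniform(-0.3, 0.3, size=20), 0.0, 1.0)
        assert cross_entropy_from_probs(p_true, y) <= cross_entropy_from_probs(p_other, y)
        assert cross_entropy_from_probs(p_other, y) >= 0.0

    def test_total_loss_arithmetic(self):
        assert total_loss(0.7, 2.0, LossConfig(lambda_=0.0)) == pytest.approx(0.7)
        assert total_loss(0.7, 2.0, LossConfig(lambda_=0.01)) == pytest.approx(0.72)
        assert total_loss(0.3, 0.4, LossConfig(lambda_=1.0)) == pytest.approx(0.7)


class TestLateFusion:
    def test_degenerate_weight_keeps_functional_prediction(self):
        pred = late_fusion_forward((0.8, 0.2), (0.3, 0.7), w_f=1.0)
        assert pred.probabilities == pytest.approx((0.8, 0.2))

    def test_symmetric_average(self):
        pred = late_fusion_forward((0.8, 0.2), (0.2, 0.8), w_f=0.5)
        assert pred.probabilities == pytest.approx((0.5, 0.5))

    def test_convex_combination_oracle(self):
        pred = late_fusion_forward((0.9, 0.1), (0.25, 0.75), w_f=0.2)
        assert pred.probabilities == pytest.approx(
            (0.2 * 0.9 + 0.8 * 0.25, 0.2 * 0.1 + 0.8 * 0.75), rel=1e-12
        )

    def test_weight_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            late_fusion_forward((0.5, 0.5), (0.5, 0.5), w_f=1.5)
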