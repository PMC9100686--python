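"""Cross-modal adaptation and fusion.

The adaptation loss is the maximum mean discrepancy between the batch of
functional embeddings and the batch of structural embeddings.  With the
default linear kernel (identity feature map) it is the Euclidean distance
between the two batch means — the deep-domain-confusion form; an RBF kernel
with median-heuristic bandwidth is available behind config.  The printed
form of the loss is an (unsquared) norm; a squared variant exists for
smoother gradients.

Feature-level fusion concatenates the two 64-dim embeddings
(functional first), passes them through FC(64)+ReLU and FC(2), and applies a
softmax.  Decision-level fusion instead averages per-branch softmax outputs
with a convex weight.  The total training objective is
``L = L_C + lambda * L_M`` with binary cross-entropy L_C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, ParameterError
from .nn import Linear, Param, ReLU, softmax
from .types import BranchFeature, FeatureBatch, Prediction

__all__ = [
    "LossConfig",
    "FusionHead",
    "mmd_loss",
    "mmd_loss_with_grad",
    "fuse_and_classify",
    "cross_entropy_loss",
    "cross_entropy_from_probs",
    "total_loss",
    "late_fusion_forward",
]

_CLIP = 1e-7


@dataclass
class LossConfig:
    """Loss arithmetic: lambda weights the MMD term against cross-entropy."""

    lambda_: float = 0.01
    mmd_kernel: str = "linear"
    mmd_squared: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_) or self.lambda_ < 0:
            raise ParameterError(f"lambda must be finite and >= 0, got {self.lambda_}")
        if self.mmd_kernel not in ("linear", "rbf"):
            raise ParameterError(f"unknown MMD kernel {self.mmd_kernel!r}")


def _mmd_linear(f: np.ndarray, s: np.ndarray, squared: bool):
    diff = f.mean(axis=0) - s.mean(axis=0)
    sq = float(diff @ diff)
    if squared:
        value = sq
        dmu = 2.0 * diff
    else:
        value = float(np.sqrt(sq))
        dmu = diff / value if value > 1e-12 else np.zeros_like(diff)
    return value, dmu / f.shape[0], -dmu / s.shape[0]


def _rbf_terms(x: np.ndarray, y: np.ndarray, sigma2: float):
    d = x[:, None, :] - y[None, :, :]
    k = np.exp(-(d**2).sum(-1) / (2.0 * sigma2))
    return k, d


def _mmd_rbf(f: np.ndarray, s: np.ndarray, squared: bool):
    # median-heuristic bandwidth over pooled pairwise squared distances
    pooled = np.concatenate([f, s], axis=0)
    dist2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
    off = dist2[~np.eye(len(pooled), dtype=bool)]
    sigma2 = float(np.median(off)) / 2.0 if off.size and np.median(off) > 0 else 1.0
    nf, ns = f.shape[0], s.shape[0]
    kff, dff = _rbf_terms(f, f, sigma2)
    kss, dss = _rbf_terms(s, s, sigma2)
    kfs, dfs = _rbf_terms(f, s, sigma2)
    sq = float(kff.mean() + kss.mean() - 2.0 * kfs.mean())
    sq = max(sq, 0.0)
    # d k(x, y) / dx = -k * (x - y) / sigma2 ; x appears on both sides of kff
    dmm_df = (
        -2.0 * (kff[:, :, None] * dff).sum(axis=1) / (nf**2 * sigma2)
        + 2.0 * (kfs[:, :, None] * dfs).sum(axis=1) / (nf * ns * sigma2)
    )
    dmm_ds = (
        -2.0 * (kss[:, :, None] * dss).sum(axis=1) / (ns**2 * sigma2)
        + 2.0 * (kfs[:, :, None] * (-dfs)).sum(axis=0) / (nf * ns * sigma2)
    )
    if squared:
        return sq, dmm_df, dmm_ds
    value = float(np.sqrt(sq))
    if value <= 1e-12:
        return value, np.zeros_like(f), np.zeros_like(s)
    return value, dmm_df / (2.0 * value), dmm_ds / (2.0 * value)


def mmd_loss_with_grad(
    f_values: np.ndarray, s_values: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """MMD between two feature stacks plus its gradients w.r.t. each stack."""
    cfg = cfg if cfg is not None else LossConfig()
    f = np.asarray(f_values, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if f.ndim != 2 or s.ndim != 2 or f.shape[0] == 0 or s.shape[0] == 0:
        raise ContractViolationError("MMD expects two nonempty 2-D feature batches")
    if f.shape[1] != s.shape[1]:
        raise ContractViolationError(
            f"MMD feature widths differ: {f.shape[1]} vs {s.shape[1]}"
        )
    if cfg.mmd_kernel == "linear":
        value, dmu_f, dmu_s = _mmd_linear(f, s, cfg.mmd_squared)
        df = np.broadcast_to(dmu_f, f.shape).copy()
        ds = np.broadcast_to(dmu_s, s.shape).copy()
        return value, df, ds
    return _mmd_rbf(f, s, cfg.mmd_squared)


def mmd_loss(
    f_batch: FeatureBatch, s_batch: FeatureBatch, cfg: LossConfig | None = None
) -> float:
    """Maximum mean discrepancy between the functional and structural batches.

    Nonnegative; exactly zero for identical batches; with the linear kernel
    and singleton batches it reduces to the Euclidean distance between the
    two feature vectors.
    """
    value, _, _ = mmd_loss_with_grad(f_batch.values, s_batch.values, cfg)
    return value


class FusionHead:
    """FC(hidden) + ReLU + FC(n_classes); a softmax turns logits into probabilities.

    The same head shape serves feature-level fusion (input 128), the
    single-modality variants (input 64), and the per-branch classifiers of
    decision-level fusion.
    """

    def __init__(
        self,
        d_in: int = 128,
        hidden: int = 64,
        n_classes: int = 2,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
        name: str = "fusion",
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(d_in, hidden, rng, dtype, name=f"{name}.fc1")
        self.relu = ReLU()
        self.fc2 = Linear(hidden, n_classes, rng, dtype, name=f"{name}.fc2")

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        return self.fc2.forward(self.relu.forward(self.fc1.forward(x, mode), mode), mode)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.fc2.backward(grad)))

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()


def fuse_and_classify(
    f1: BranchFeature,
    f2: BranchFeature,
    head: FusionHead,
    mode: str = "eval",
    true_label: int | None = None,
) -> Prediction:
    """Concatenate (functional first, structural second), classify, softmax."""
    if f1.modality != "functional" or f2.modality != "structural":
        raise ContractViolationError(
            "fusion expects (functional, structural) features in that order"
        )
    fused = np.concatenate([f1.values, f2.values])[None, :]
    probs = softmax(head.forward(fused, mode))[0]
    return Prediction(
        subject_id=f1.subject_id or f2.subject_id,
        probabilities=(float(probs[0]), float(probs[1])),
        predicted_label=int(np.argmax(probs)),
        true_label=true_label,
    )


def cross_entropy_from_probs(p1: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of class-1 probabilities against 0/1 labels."""
    p = np.clip(np.asarray(p1, dtype=float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cross_entropy_loss(preds: list[Prediction]) -> float:
    """Mean binary cross-entropy over predictions carrying true labels."""
    if not preds:
        raise ContractViolationError("cross-entropy needs at least one prediction")
    if any(p.true_label is None for p in preds):
        raise ContractViolationError("cross-entropy needs true labels on every prediction")
    p1 = np.array([p.p1 for p in preds])
    y = np.array([p.true_label for p in preds])
    return cross_entropy_from_probs(p1, y)


def total_loss(l_c: float, l_m: float, cfg: LossConfig | None = None) -> float:
    """Total objective L = L_C + lambda * L_M."""
    cfg = cfg if cfg is not None else LossConfig()
    if not (np.isfinite(l_c) and np.isfinite(l_m)):
        raise ContractViolationError("loss terms must be finite")
    return float(l_c + cfg.lambda_ * l_m)


def late_fusion_forward(
    f_prob: tuple[float, float],
    s_prob: tuple[float, float],
    w_f: float,
    subject_id: str = "",
    true_label: int | None = None,
) -> Prediction:
    """Decision-level fusion: convex combination of the two branch softmaxes."""
    if not 0.0 <= w_f <= 1.0:
        raise ParameterError(f"functional weight must be in [0, 1], got {w_f}")
    f = np.asarray(f_prob, dtype=float)
    s = np.asarray(s_prob, dtype=float)
    for name, p in (("functional", f), ("structural", s)):
        if p.shape != (2,) or p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
            raise ContractViolationError(f"{name} input is not a softmax pair: {p}")
    probs = w_f * f + (1.0 - w_f) * s
    probs = probs / probs.sum()
    return Prediction(
        subject_id=subject_id,
        probabilities=(float(probs[0]), float(probs[1])),
        predicted_label=int(np.argmax(probs)),
        true_label=true_label,
    )
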