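"""Repeated-holdout evaluation protocol and statistical comparison.

The protocol: randomly hold out a test fraction (20% by default), train on
the rest, score eight metrics (ACC, SEN, SPE, BAC, PPV, NPV, F1, AUC) with
the patient class (label 1) positive, repeat with independent partitions
(10 by default) and report per-metric mean and standard deviation.  Splits
are stratified by class by default so small cohorts keep both classes in
every test set.

Per-subject test-set class-1 probabilities are retained across repeats so
two methods can be compared with a paired t-test on aligned probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _stats

from .errors import ContractViolationError, DegenerateStatisticError, ProtocolError
from .types import Prediction

__all__ = [
    "METRIC_NAMES",
    "MetricsRecord",
    "TTestResult",
    "HoldoutResult",
    "compute_metrics",
    "roc_points",
    "stratified_split",
    "repeated_holdout",
    "paired_t_test",
]

METRIC_NAMES = ("acc", "sen", "spe", "bac", "ppv", "npv", "f1", "auc")


@dataclass(frozen=True)
class MetricsRecord:
    """Eight classification metrics; undefined entries are NaN and named in
    ``undefined`` rather than silently zeroed."""

    acc: float
    sen: float
    spe: float
    bac: float
    ppv: float
    npv: float
    f1: float
    auc: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    n_pairs: int


@dataclass
class HoldoutResult:
    """Per-repeat metrics plus pooled per-subject test probabilities."""

    records: list[MetricsRecord]
    mean: dict[str, float]
    std: dict[str, float]
    predictions: list[list[Prediction]] = field(default_factory=list)

    def pooled_probabilities(self) -> tuple[list[str], np.ndarray]:
        """Class-1 probabilities of every test occurrence, ordered by repeat
        then subject id; the key list aligns runs for paired comparison."""
        keys, probs = [], []
        for repeat, preds in enumerate(self.predictions):
            for p in sorted(preds, key=lambda q: q.subject_id):
                keys.append(f"{repeat}:{p.subject_id}")
                probs.append(p.p1)
        return keys, np.asarray(probs)


def compute_metrics(preds: Sequence[Prediction]) -> MetricsRecord:
    """Confusion-table metrics and rank-based AUC from predictions.

    The patient class (label 1) is positive.  AUC uses the Mann-Whitney
    convention: tied probabilities contribute 1/2 per tied pair.
    """
    if not preds:
        raise ContractViolationError("no predictions to score")
    if any(p.true_label is None for p in preds):
        raise ContractViolationError("every prediction needs a true label")
    y = np.array([p.true_label for p in preds])
    yhat = np.array([p.predicted_label for p in preds])
    p1 = np.array([p.p1 for p in preds])
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (tp + tn) / len(y)
    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    bac = (sen + spe) / 2.0 if "sen" not in undefined and "spe" not in undefined else float("nan")
    if np.isnan(bac):
        undefined.append("bac")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sen / (ppv + sen)
    if n_pos == 0 or n_neg == 0:
        undefined.append("auc")
        auc = float("nan")
    else:
        ranks = _stats.rankdata(p1)
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return MetricsRecord(
        acc=float(acc),
        sen=float(sen),
        spe=float(spe),
        bac=float(bac),
        ppv=float(ppv),
        npv=float(npv),
        f1=float(f1),
        auc=float(auc),
        undefined=tuple(dict.fromkeys(undefined)),
    )


def roc_points(preds: Sequence[Prediction]) -> np.ndarray:
    """ROC curve points (FPR, TPR, threshold), one row per distinct class-1
    probability, ordered from the most to the least conservative threshold;
    exportable as TSV for plotting."""
    if not preds or any(p.true_label is None for p in preds):
        raise ContractViolationError("ROC needs labeled predictions")
    y = np.array([p.true_label for p in preds])
    p1 = np.array([p.p1 for p in preds])
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractViolationError("ROC needs both classes in the truth labels")
    rows = [(0.0, 0.0, np.inf)]
    for thr in np.unique(p1)[::-1]:
        yhat = p1 >= thr
        tpr = float((yhat & (y == 1)).sum() / n_pos)
        fpr = float((yhat & (y == 0)).sum() / n_neg)
        rows.append((fpr, tpr, float(thr)))
    return np.array(rows)


def stratified_split(
    labels: np.ndarray,
    test_fraction: float,
    rng: np.random.Generator,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index split; stratified keeps both classes in test."""
    labels = np.asarray(labels)
    n = len(labels)
    n_test = int(round(test_fraction * n))
    if not 0 < test_fraction < 1 or n_test < 1 or n_test >= n:
        raise ProtocolError(
            f"cannot hold out {test_fraction:.0%} of {n} subjects"
        )
    if not stratify:
        perm = rng.permutation(n)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    test_parts = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        k = int(round(test_fraction * len(members)))
        k = max(k, 1)
        if k >= len(members):
            raise ProtocolError(
                f"class {cls} has only {len(members)} subjects; cannot "
                f"hold out {test_fraction:.0%} with both classes in train and test"
            )
        test_parts.append(rng.permutation(members)[:k])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def repeated_holdout(
    cohort: Sequence,
    train_fn: Callable[[list, int], object],
    n_repeats: int = 10,
    test_fraction: float = 0.2,
    base_seed: int = 0,
    stratify: bool = True,
) -> HoldoutResult:
    """Repeated random holdout: split, train, score, summarize.

    ``train_fn(train_subjects, seed)`` must return an object with a
    ``predict(subjects) -> list[Prediction]`` method.  Repeat i uses seed
    ``base_seed + i`` for both the split and the training run.  The summary
    standard deviation is the n-1 sample standard deviation (0 for a single
    repeat).
    """
    if n_repeats < 1:
        raise ProtocolError("n_repeats must be >= 1")
    labels = np.array([s.label for s in cohort])
    if len(np.unique(labels)) < 2:
        raise ProtocolError("cohort must contain both classes")
    records: list[MetricsRecord] = []
    predictions: list[list[Prediction]] = []
    for repeat in range(n_repeats):
        seed = base_seed + repeat
        rng = np.random.default_rng(seed)
        train_idx, test_idx = stratified_split(labels, test_fraction, rng, stratify)
        model = train_fn([cohort[i] for i in train_idx], seed)
        preds = model.predict([cohort[i] for i in test_idx])
        records.append(compute_metrics(preds))
        predictions.append(preds)
    mean = {
        name: float(np.mean([r.as_dict()[name] for r in records]))
        for name in METRIC_NAMES
    }
    std = {
        name: (
            float(np.std([r.as_dict()[name] for r in records], ddof=1))
            if len(records) > 1
            else 0.0
        )
        for name in METRIC_NAMES
    }
    return HoldoutResult(records=records, mean=mean, std=std, predictions=predictions)


def paired_t_test(
    probs_a: Sequence[float], probs_b: Sequence[float]
) -> TTestResult:
    """Paired two-sided t-test on aligned probability sequences.

    t = mean(d) / (sd(d) / sqrt(n)) with sd the n-1 sample standard
    deviation of the pairwise differences; p is two-sided from the t
    distribution with n-1 degrees of freedom.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractViolationError("paired t-test needs two equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ContractViolationError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateStatisticError(
            "paired differences have zero variance; the t statistic is undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(_stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t_statistic=float(t), p_value=min(p, 1.0), n_pairs=n)
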