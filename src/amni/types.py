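"""Shared dataclasses passed between branches, fusion and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ContractViolationError

__all__ = ["BranchFeature", "Prediction", "FeatureBatch", "VolumeImage", "MultimodalSubject"]


@dataclass(frozen=True)
class BranchFeature:
    """One subject's embedding from one branch (64-dim by default)."""

    subject_id: str
    modality: str  # "functional" | "structural"
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if self.modality not in ("functional", "structural"):
            raise ContractViolationError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(values)):
            raise ContractViolationError("branch feature contains non-finite values")


@dataclass(frozen=True)
class Prediction:
    """Softmax output for one subject; class 1 is the patient class."""

    subject_id: str
    probabilities: tuple[float, float]
    predicted_label: int
    true_label: int | None = None

    def __post_init__(self) -> None:
        p0, p1 = (float(p) for p in self.probabilities)
        object.__setattr__(self, "probabilities", (p0, p1))
        if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
            raise ContractViolationError("probabilities must lie in [0, 1]")
        if abs(p0 + p1 - 1.0) > 1e-9:
            raise ContractViolationError("probabilities must sum to 1")
        if self.predicted_label not in (0, 1):
            raise ContractViolationError("predicted label must be 0 or 1")
        if self.true_label is not None and self.true_label not in (0, 1):
            raise ContractViolationError("true label must be 0 or 1")

    @property
    def p1(self) -> float:
        """Probability of the positive (patient) class."""
        return self.probabilities[1]


@dataclass(frozen=True)
class FeatureBatch:
    """A stack of same-modality embeddings entering the MMD loss."""

    modality: str
    values: np.ndarray  # (batch, width)
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] == 0:
            raise ContractViolationError(
                f"feature batch must be nonempty 2-D, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ContractViolationError("feature batch contains non-finite values")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class VolumeImage:
    """A subject's 3-D gray-matter intensity volume."""

    subject_id: str
    values: np.ndarray  # (H, W, D)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ContractViolationError(
                f"volume for {self.subject_id!r} must be 3-D, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ContractViolationError(
                f"volume for {self.subject_id!r} contains non-finite values"
            )
        object.__setattr__(
            self, "voxel_size", tuple(float(v) for v in self.voxel_size)
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.values.shape)  # type: ignore[return-value]


@dataclass
class MultimodalSubject:
    """One cohort record: a label plus whichever modalities are available."""

    subject_id: str
    label: int
    time_series: Any = None  # TimeSeriesMatrix | None
    volume: VolumeImage | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ContractViolationError(
                f"label for {self.subject_id!r} must be 0 or 1, got {self.label}"
            )
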