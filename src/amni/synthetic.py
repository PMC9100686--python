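"""Seeded synthetic multimodal cohorts.

The generator emulates the statistical structure the classifier assumes,
without physiological detail:

* the functional modality is a zero-mean multivariate normal time series
  whose inter-ROI covariance is a community-block matrix; the patient class
  shifts the covariance on a chosen edge subset (positive-definiteness is
  enforced by convex shrinkage toward the base covariance, bisected on the
  minimum eigenvalue).  AR(1) temporal smoothing models BOLD autocorrelation
  while leaving the stationary covariance untouched — only the covariance
  matters to Pearson connectivity;
* the structural modality is a smooth ellipsoidal "brain" intensity profile
  plus Gaussian noise; the patient class adds an intensity offset inside
  chosen spherical blobs (negative offsets model atrophy).

``modality_signal_split`` routes, per patient, which modality expresses the
class effect: a fraction ``split`` of patients express only the functional
covariance effect, the remainder only the structural blob effect.  At
split = 1 the volumes carry no class signal, at split = 0 the time series
carry none, and at split = 0.5 neither single modality can separate the
classes fully while both together can — which makes multimodal superiority
a testable property of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import TimeSeriesMatrix
from .errors import ConfigError, DegenerateInputError
from .types import MultimodalSubject, VolumeImage

__all__ = [
    "Blob",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "base_covariance",
    "effect_covariance",
    "generate_timeseries",
    "generate_volume",
    "generate_cohort",
]

_PD_FLOOR = 1e-6


@dataclass(frozen=True)
class Blob:
    """A spherical intensity-offset region, in voxel coordinates."""

    center: tuple[float, float, float]
    radius: float
    delta: float


@dataclass
class SyntheticCohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the desk-scale conditions used throughout the test suite:
    150 + 150 subjects, 20 ROIs x 120 time points, 24 x 28 x 24 volumes.
    Full-size cohorts (112 ROIs, 121 x 145 x 121 volumes) are supported by
    overriding the fields.
    """

    n_class0: int = 150
    n_class1: int = 150
    n_rois: int = 20
    n_timepoints: int = 120
    volume_shape: tuple[int, int, int] = (24, 28, 24)
    # the class effect couples two whole ROI communities (every pair between
    # the first two 5-ROI blocks): distributed network-level dysconnectivity
    # rather than single anomalous edges, which is also the regime a
    # weight-shared graph convolution is built to detect
    functional_effect_edges: list[tuple[int, int]] = field(
        default_factory=lambda: [(i, j) for i in range(5) for j in range(5, 10)]
    )
    functional_effect_delta: float = 0.4
    structural_effect_blobs: list[Blob] = field(
        default_factory=lambda: [
            Blob(center=(9.0, 14.0, 12.0), radius=4.0, delta=-0.4),
            Blob(center=(16.0, 13.0, 11.0), radius=3.0, delta=0.35),
        ]
    )
    noise_sd: float = 0.1
    temporal_ar_coeff: float = 0.3
    modality_signal_split: float = 0.5
    community_size: int = 5
    within_community_cov: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class0 < 1 or self.n_class1 < 1:
            raise ConfigError("both class counts must be positive")
        if self.n_rois < 2 or self.n_timepoints < 3:
            raise ConfigError("need at least 2 ROIs and 3 time points")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 4:
            raise ConfigError("volume shape must be three dims of at least 4 voxels")
        for i, j in self.functional_effect_edges:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois) or i == j:
                raise ConfigError(f"effect edge ({i}, {j}) outside the {self.n_rois}-ROI range")
        for blob in self.structural_effect_blobs:
            if blob.radius <= 0:
                raise ConfigError("blob radius must be positive")
            for c, dim in zip(blob.center, self.volume_shape):
                if c - blob.radius < -0.5 or c + blob.radius > dim - 0.5:
                    raise ConfigError(
                        f"blob at {blob.center} with radius {blob.radius} "
                        f"extends outside the {self.volume_shape} volume"
                    )
        if not 0.0 <= self.temporal_ar_coeff < 1.0:
            raise ConfigError("AR(1) coefficient must be in [0, 1)")
        if not 0.0 <= self.modality_signal_split <= 1.0:
            raise ConfigError("modality_signal_split must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be >= 0")


# alias: a generated record is an ordinary multimodal subject with
# ``ground_truth`` filled in
SyntheticSubject = MultimodalSubject


def base_covariance(cfg: SyntheticCohortConfig) -> np.ndarray:
    """Community-block covariance: unit variance, ``within_community_cov``
    inside consecutive blocks of ``community_size`` ROIs, zero elsewhere."""
    n = cfg.n_rois
    cov = np.zeros((n, n))
    for start in range(0, n, cfg.community_size):
        stop = min(start + cfg.community_size, n)
        cov[start:stop, start:stop] = cfg.within_community_cov
    np.fill_diagonal(cov, 1.0)
    return cov


def effect_covariance(cfg: SyntheticCohortConfig) -> tuple[np.ndarray, float]:
    """Patient-class covariance: base plus delta on the effect edges,
    shrunk toward the base just enough to stay positive definite.

    Returns the covariance and the shrinkage coefficient actually applied
    (1.0 means the full delta was admissible).
    """
    base = base_covariance(cfg)
    bump = np.zeros_like(base)
    for i, j in cfg.functional_effect_edges:
        bump[i, j] += cfg.functional_effect_delta
        bump[j, i] += cfg.functional_effect_delta

    def min_eig(alpha: float) -> float:
        return float(np.linalg.eigvalsh(base + alpha * bump)[0])

    if min_eig(1.0) >= _PD_FLOOR:
        return base + bump, 1.0
    lo, hi = 0.0, 1.0  # min_eig(0) >= floor by construction
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if min_eig(mid) >= _PD_FLOOR:
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        raise DegenerateInputError(
            "effect covariance cannot be made positive definite"
        )
    return base + lo * bump, lo


def _sample_timeseries(
    cov: np.ndarray, m: int, ar: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1)-smoothed Gaussian series with stationary covariance ``cov``."""
    chol = np.linalg.cholesky(cov)
    innovations = rng.standard_normal((m, cov.shape[0])) @ chol.T
    if ar == 0.0:
        return innovations
    series = np.empty_like(innovations)
    series[0] = innovations[0]
    scale = np.sqrt(1.0 - ar**2)
    for t in range(1, m):
        series[t] = ar * series[t - 1] + scale * innovations[t]
    return series


def generate_timeseries(
    cfg: SyntheticCohortConfig,
    label: int,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> TimeSeriesMatrix:
    """One subject's ROI time series; ``label`` selects which covariance
    generates it (1 = effect covariance, 0 = base)."""
    cov = effect_covariance(cfg)[0] if label == 1 else base_covariance(cfg)
    values = _sample_timeseries(cov, cfg.n_timepoints, cfg.temporal_ar_coeff, rng)
    return TimeSeriesMatrix(subject_id=subject_id, values=values)


def _brain_profile(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(dim, dtype=float) for dim in shape], indexing="ij"
    )
    r2 = np.zeros(shape)
    for grid, dim in zip(grids, shape):
        half = (dim - 1) / 2.0
        r2 += ((grid - half) / (0.95 * half)) ** 2
    return 0.8 * np.clip(1.0 - r2, 0.0, None)


def blob_mask(shape: tuple[int, int, int], blob: Blob) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(dim, dtype=float) for dim in shape], indexing="ij"
    )
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, blob.center))
    return dist2 <= blob.radius**2


def generate_volume(
    cfg: SyntheticCohortConfig,
    label: int,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> VolumeImage:
    """One subject's gray-matter volume; ``label`` = 1 applies the blob offsets."""
    values = _brain_profile(cfg.volume_shape).copy()
    if label == 1:
        for blob in cfg.structural_effect_blobs:
            values[blob_mask(cfg.volume_shape, blob)] += blob.delta
    if cfg.noise_sd > 0:
        values = values + cfg.noise_sd * rng.standard_normal(cfg.volume_shape)
    return VolumeImage(subject_id=subject_id, values=values, voxel_size=(1.0, 1.0, 1.0))


def generate_cohort(cfg: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """The full two-class cohort, a pure function of (config, seed).

    Class-0 subjects express no effect.  Each class-1 subject expresses the
    class effect in exactly one modality, chosen by the signal-split routing;
    ``ground_truth`` records the route and the effects actually applied.
    """
    n0, n1 = cfg.n_class0, cfg.n_class1
    seeds = np.random.SeedSequence(cfg.seed).spawn(1 + n0 + n1)
    route_rng = np.random.default_rng(seeds[0])
    n_functional = int(round(cfg.modality_signal_split * n1))
    routes = np.array(["functional"] * n_functional + ["structural"] * (n1 - n_functional))
    route_rng.shuffle(routes)
    subjects: list[SyntheticSubject] = []
    labels = [0] * n0 + [1] * n1
    route_iter = iter(routes)
    for idx, label in enumerate(labels):
        rng = np.random.default_rng(seeds[1 + idx])
        subject_id = f"sub-{idx:04d}"
        if label == 0:
            func_label = struct_label = 0
            route = None
        else:
            route = next(route_iter)
            func_label = 1 if route == "functional" else 0
            struct_label = 1 if route == "structural" else 0
        ts = generate_timeseries(cfg, func_label, rng, subject_id)
        vol = generate_volume(cfg, struct_label, rng, subject_id)
        subjects.append(
            SyntheticSubject(
                subject_id=subject_id,
                label=label,
                time_series=ts,
                volume=vol,
                ground_truth={
                    "route": route,
                    "functional_edges": list(cfg.functional_effect_edges)
                    if func_label
                    else [],
                    "structural_blobs": [
                        (blob.center, blob.radius, blob.delta)
                        for blob in cfg.structural_effect_blobs
                    ]
                    if struct_label
                    else [],
                },
            )
        )
    return subjects
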