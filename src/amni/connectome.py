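"""Functional connectome construction.

Turns per-subject ROI BOLD time series into Pearson functional connectivity
matrices and into the graph encodings (adjacency + node features) consumed by
the spectral graph-convolution branch.  Three sparsification strategies are
supported:

``knn``
    keep, for every node, the edges to its k strongest neighbours (by
    connectivity strength), then symmetrize by logical OR;
``threshold``
    keep every edge whose strength exceeds a fixed threshold q;
``full``
    keep the dense edge-weighted graph with weights ``|b_ij|``.

"Strength" is the absolute Pearson coefficient by default (a strong
anticorrelation is a strong connection); a config switch selects signed
selection instead.  Self-loops are never stored in the adjacency; they are
added once, inside :func:`normalize_adjacency`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, DegenerateInputError, ParameterError

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "ConnectivityGraph",
    "NormalizedAdjacency",
    "GraphConfig",
    "pearson_fcn",
    "build_knn_graph",
    "build_threshold_graph",
    "build_full_graph",
    "build_graph",
    "normalize_adjacency",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Per-subject ROI time series: ``values`` is M time points x N ROIs.

    ROIs are indexed 0-based internally and reported 1-based in messages.
    """

    subject_id: str
    values: np.ndarray
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ContractViolationError(
                f"time series for {self.subject_id!r} must be 2-D "
                f"(time points x ROIs), got shape {values.shape}"
            )
        m, n = values.shape
        if m < 3:
            raise ContractViolationError(
                f"time series for {self.subject_id!r} needs at least 3 time "
                f"points, got {m}"
            )
        if n < 2:
            raise ContractViolationError(
                f"time series for {self.subject_id!r} needs at least 2 ROIs, got {n}"
            )
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError(
                f"time series for {self.subject_id!r} contains non-finite values"
            )
        if not self.roi_names:
            object.__setattr__(
                self, "roi_names", tuple(f"ROI{i + 1}" for i in range(n))
            )
        if len(self.roi_names) != n:
            raise ContractViolationError(
                f"{len(self.roi_names)} ROI names for {n} columns "
                f"(subject {self.subject_id!r})"
            )
        variances = values.var(axis=0)
        dead = np.flatnonzero(variances == 0.0)
        if dead.size:
            i = int(dead[0])
            raise DegenerateInputError(
                f"ROI {i + 1} ({self.roi_names[i]!r}) of subject "
                f"{self.subject_id!r} has zero variance; Pearson connectivity "
                "is undefined for constant signals"
            )

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_rois(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N connectivity matrix with unit diagonal, entries in [-1, 1]."""

    values: np.ndarray
    kind: str = "pearson"
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ContractViolationError(
                f"connectivity matrix must be square, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError("connectivity matrix contains non-finite values")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ContractViolationError("connectivity matrix must be symmetric")
        if np.abs(values).max() > 1.0 + 1e-8:
            raise ContractViolationError(
                "connectivity entries must lie in [-1, 1]"
            )
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise ContractViolationError("connectivity diagonal must be 1")
        # canonicalize: exact symmetry, exact unit diagonal, clipped range
        values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
        object.__setattr__(self, "values", values)
        if not self.roi_names:
            object.__setattr__(
                self,
                "roi_names",
                tuple(f"ROI{i + 1}" for i in range(values.shape[0])),
            )
        if len(self.roi_names) != values.shape[0]:
            raise ContractViolationError("ROI name count does not match matrix size")

    @property
    def n_rois(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class ConnectivityGraph:
    """Graph encoding of one subject's connectome.

    ``adjacency`` is binary for the knn/threshold strategies and nonnegative
    real (``|b_ij|``) for the fully-connected strategy; its diagonal is always
    zero.  ``node_features`` is exactly the connectivity matrix (X = B): node
    i is described by its connectivity profile to every ROI.
    """

    adjacency: np.ndarray
    node_features: np.ndarray
    strategy: str
    strategy_param: float | None = None

    def __post_init__(self) -> None:
        adjacency = np.asarray(self.adjacency, dtype=float)
        features = np.asarray(self.node_features, dtype=float)
        object.__setattr__(self, "adjacency", adjacency)
        object.__setattr__(self, "node_features", features)
        if self.strategy not in ("knn", "threshold", "full"):
            raise ParameterError(f"unknown graph strategy {self.strategy!r}")
        n = adjacency.shape[0]
        if adjacency.shape != (n, n) or features.shape[0] != n:
            raise ContractViolationError("adjacency/node-feature shape mismatch")
        if not np.allclose(adjacency, adjacency.T, atol=1e-12):
            raise ContractViolationError("adjacency must be symmetric")
        if np.any(np.diag(adjacency) != 0.0):
            raise ContractViolationError(
                "adjacency diagonal must be zero; self-loops are added at "
                "normalization time only"
            )
        if adjacency.min() < 0.0:
            raise ContractViolationError("adjacency must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return int(self.adjacency.shape[0])


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically normalized adjacency with self-loops:
    ``D^{-1/2} (A + I) D^{-1/2}`` with D the degree matrix of A + I."""

    values: np.ndarray
    includes_self_loops: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ContractViolationError("normalized adjacency must be finite")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ContractViolationError("normalized adjacency must be symmetric")


@dataclass
class GraphConfig:
    """How to turn a connectivity matrix into a graph.

    k is not dictated by the method itself; 10 is a common sparsity for
    connectomes of ~100 nodes.  ``absolute`` selects whether edge strength is
    |b_ij| (default) or the signed coefficient.
    """

    strategy: str = "knn"
    k: int = 10
    q: float = 0.2
    absolute: bool = True


def pearson_fcn(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson functional connectivity matrix of a time-series matrix.

    Entry (i, j) is the Pearson correlation between the BOLD series of ROIs i
    and j, i.e. the cosine of the mean-centered series.  The result is
    symmetric with unit diagonal and entries in [-1, 1].
    """
    centered = ts.values - ts.values.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:  # unreachable through the validated type; defend anyway
        i = int(dead[0])
        raise DegenerateInputError(
            f"ROI {i + 1} ({ts.roi_names[i]!r}) has zero variance"
        )
    corr = (centered.T @ centered) / np.outer(norms, norms)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(values=corr, kind="pearson", roi_names=ts.roi_names)


def _edge_strength(b: ConnectivityMatrix, absolute: bool) -> np.ndarray:
    return np.abs(b.values) if absolute else b.values.copy()


def build_knn_graph(
    b: ConnectivityMatrix, k: int, absolute: bool = True
) -> ConnectivityGraph:
    """KNN sparsification: each node keeps edges to its k strongest neighbours.

    The per-node top-k relation is directed; the adjacency is symmetrized by
    logical OR (an edge survives if either endpoint selected it), so every
    node ends with degree >= k.  Ties at the k-th rank break toward the lower
    ROI index for cross-platform determinism.
    """
    n = b.n_rois
    if not (1 <= int(k) <= n - 1):
        raise ParameterError(f"k must be in [1, {n - 1}] for {n} ROIs, got {k}")
    k = int(k)
    strength = _edge_strength(b, absolute)
    np.fill_diagonal(strength, -np.inf)
    adjacency = np.zeros((n, n))
    indices = np.arange(n)
    for i in range(n):
        # sort by strength descending, ties by lower index
        order = np.lexsort((indices, -strength[i]))
        adjacency[i, order[:k]] = 1.0
    adjacency = np.maximum(adjacency, adjacency.T)
    np.fill_diagonal(adjacency, 0.0)
    return ConnectivityGraph(
        adjacency=adjacency,
        node_features=b.values.copy(),
        strategy="knn",
        strategy_param=float(k),
    )


def build_threshold_graph(
    b: ConnectivityMatrix, q: float = 0.2, absolute: bool = True
) -> ConnectivityGraph:
    """Binary adjacency: a_ij = 1 iff the connection strength exceeds q (i != j)."""
    if q < 0:
        raise ParameterError(f"threshold q must be >= 0, got {q}")
    strength = _edge_strength(b, absolute)
    adjacency = (strength > float(q)).astype(float)
    np.fill_diagonal(adjacency, 0.0)
    return ConnectivityGraph(
        adjacency=adjacency,
        node_features=b.values.copy(),
        strategy="threshold",
        strategy_param=float(q),
    )


def build_full_graph(b: ConnectivityMatrix) -> ConnectivityGraph:
    """Dense edge-weighted graph with adjacency |B| and zero diagonal."""
    adjacency = np.abs(b.values)
    np.fill_diagonal(adjacency, 0.0)
    return ConnectivityGraph(
        adjacency=adjacency,
        node_features=b.values.copy(),
        strategy="full",
        strategy_param=None,
    )


def build_graph(b: ConnectivityMatrix, cfg: GraphConfig) -> ConnectivityGraph:
    """Dispatch on :class:`GraphConfig.strategy`."""
    if cfg.strategy == "knn":
        return build_knn_graph(b, cfg.k, absolute=cfg.absolute)
    if cfg.strategy == "threshold":
        return build_threshold_graph(b, cfg.q, absolute=cfg.absolute)
    if cfg.strategy == "full":
        return build_full_graph(b)
    raise ParameterError(f"unknown graph strategy {cfg.strategy!r}")


def normalize_adjacency(g: ConnectivityGraph) -> NormalizedAdjacency:
    """Symmetric normalization with self-loops.

    Returns ``D^{-1/2} (A + I) D^{-1/2}`` where D is the diagonal degree
    matrix of A + I.  Including the loop in the degree keeps every degree
    strictly positive, so the result is always finite; its spectral radius is
    at most 1.
    """
    a_hat = g.adjacency + np.eye(g.n_nodes)
    inv_sqrt_deg = 1.0 / np.sqrt(a_hat.sum(axis=1))
    values = a_hat * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]
    return NormalizedAdjacency(values=values, includes_self_loops=True)
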