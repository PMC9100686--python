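"""Functional branch: spectral graph convolutions over the connectome.

A stack of layers ``H^(l+1) = ReLU(A_norm H^(l) W^(l))`` on the normalized
adjacency, a permutation-invariant mean||max readout over nodes, and one
fully-connected head mapping the pooled 2*d vector to the 64-dim functional
embedding that enters adaptation and fusion.

The module exposes both a batched trainable :class:`GCNBranch` and pure
single-subject functions (:func:`gcn_layer_forward`, :func:`graph_readout`,
...) that define the numerical contract and serve as cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectivityGraph, NormalizedAdjacency, normalize_adjacency
from .errors import ContractViolationError
from .nn import Dropout, Linear, Param, ReLU, glorot_uniform
from .types import BranchFeature

__all__ = [
    "GCNBranchConfig",
    "GCNBranch",
    "gcn_layer_forward",
    "gcn_stack_forward",
    "graph_readout",
    "gcn_head_forward",
]


@dataclass
class GCNBranchConfig:
    """Architecture of the functional branch.

    Two 64-unit graph-convolution layers; head maps the 128-dim readout to a
    64-dim embedding so the two modality features are like-sized for MMD.
    """

    layer_widths: list[int] = field(default_factory=lambda: [64, 64])
    head_width: int = 64
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.layer_widths or any(w <= 0 for w in self.layer_widths):
            raise ContractViolationError("layer widths must be positive and nonempty")
        if self.head_width <= 0:
            raise ContractViolationError("head width must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ContractViolationError("dropout rate must be in [0, 1)")


def gcn_layer_forward(
    h: np.ndarray, a_norm: NormalizedAdjacency, w: np.ndarray
) -> np.ndarray:
    """One spectral graph-convolution layer: ReLU(A_norm @ H @ W).

    Graph convolutions carry no bias term.
    """
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    a = a_norm.values
    if h.shape[0] != a.shape[0]:
        raise ContractViolationError(
            f"node count mismatch: H has {h.shape[0]} rows, A is {a.shape[0]}x{a.shape[1]}"
        )
    if h.shape[1] != w.shape[0]:
        raise ContractViolationError(
            f"feature width mismatch: H has {h.shape[1]} columns, W has {w.shape[0]} rows"
        )
    return np.maximum(a @ h @ w, 0.0)


def gcn_stack_forward(g: ConnectivityGraph, branch: "GCNBranch") -> np.ndarray:
    """Compose the branch's graph-convolution layers on one subject's graph.

    Node features are the connectivity rows (X = B); returns the N x d_last
    node-representation matrix before readout.
    """
    a_norm = normalize_adjacency(g)
    h = g.node_features
    for layer in branch.layers:
        h = gcn_layer_forward(h, a_norm, layer.W.value)
    return h


def graph_readout(z: np.ndarray) -> np.ndarray:
    """Mean||max readout: concatenate channel-wise mean and max over nodes."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ContractViolationError(
            f"readout expects a nonempty N x d matrix, got shape {z.shape}"
        )
    return np.concatenate([z.mean(axis=0), z.max(axis=0)])


def gcn_head_forward(pooled: np.ndarray, branch: "GCNBranch") -> BranchFeature:
    """Affine head + ReLU mapping the pooled 2*d vector to the functional embedding."""
    pooled = np.asarray(pooled, dtype=float).ravel()
    out = branch.head.forward(pooled[None, :], mode="eval")
    return BranchFeature(
        subject_id="", modality="functional", values=np.maximum(out[0], 0.0)
    )


class _GCNLayer:
    """Batched graph-convolution layer with cached intermediates for backward."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        dtype=np.float64,
        name: str = "gcn",
    ) -> None:
        self.W = Param(glorot_uniform((d_in, d_out), d_in, d_out, rng, dtype), name=f"{name}.W")

    def forward(self, a: np.ndarray, h: np.ndarray, mode: str = "train") -> np.ndarray:
        # a: (B, N, N) symmetric; h: (B, N, d_in)
        s = np.matmul(a, h)
        z = np.matmul(s, self.W.value)
        self._a, self._s = a, s
        self._mask = z > 0
        return z * self._mask

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        dz = grad * self._mask
        self.W.grad += np.einsum("bni,bnj->ij", self._s, dz)
        if not need_input_grad:
            return None
        ds = np.matmul(dz, self.W.value.T)
        # a is symmetric, but transpose explicitly for clarity
        return np.matmul(self._a.transpose(0, 2, 1), ds)

    def params(self) -> list[Param]:
        return [self.W]


class GCNBranch:
    """Trainable functional branch operating on batches of graphs.

    ``forward`` takes the stacked normalized adjacencies (B, N, N) and node
    features (B, N, N) and returns the (B, head_width) embedding matrix.
    """

    def __init__(
        self,
        n_rois: int,
        cfg: GCNBranchConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ) -> None:
        self.cfg = cfg if cfg is not None else GCNBranchConfig()
        self.n_rois = int(n_rois)
        rng = rng if rng is not None else np.random.default_rng(0)
        widths = [self.n_rois] + list(self.cfg.layer_widths)
        self.layers = [
            _GCNLayer(widths[i], widths[i + 1], rng, dtype, name=f"gcn.layer{i}")
            for i in range(len(self.cfg.layer_widths))
        ]
        self.head = Linear(
            2 * widths[-1], self.cfg.head_width, rng, dtype, name="gcn.head"
        )
        self.head_relu = ReLU()
        self.dropout = Dropout(self.cfg.dropout_rate, rng=np.random.default_rng(rng.integers(2**31)))

    # -- forward / backward -------------------------------------------------
    def forward(self, a: np.ndarray, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if a.ndim != 3 or x.ndim != 3:
            raise ContractViolationError("GCN branch expects batched (B, N, N) inputs")
        if x.shape[2] != self.n_rois:
            raise ContractViolationError(
                f"node features must have width {self.n_rois}, got {x.shape[2]}"
            )
        h = x
        for layer in self.layers:
            h = layer.forward(a, h, mode)
        self._z = h  # (B, N, d)
        mean = h.mean(axis=1)
        self._argmax = h.argmax(axis=1)  # (B, d)
        mx = np.take_along_axis(h, self._argmax[:, None, :], axis=1)[:, 0, :]
        pooled = np.concatenate([mean, mx], axis=1)
        pooled = self.dropout.forward(pooled, mode)
        out = self.head.forward(pooled, mode)
        return self.head_relu.forward(out, mode)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head_relu.backward(grad)
        grad = self.head.backward(grad)
        grad = self.dropout.backward(grad)
        d = self._z.shape[2]
        n = self._z.shape[1]
        dmean, dmax = grad[:, :d], grad[:, d:]
        dz = np.repeat(dmean[:, None, :] / n, n, axis=1)
        np.put_along_axis(
            dz,
            self._argmax[:, None, :],
            np.take_along_axis(dz, self._argmax[:, None, :], axis=1) + dmax[:, None, :],
            axis=1,
        )
        for i, layer in reversed(list(enumerate(self.layers))):
            dz = layer.backward(dz, need_input_grad=(i > 0))

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out
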