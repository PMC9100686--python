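"""Structural branch: 3-D CNN over gray-matter volumes.

Four convolution blocks (3x3x3 same-padding conv, batch normalization, ReLU,
2x2x2 stride-2 max-pool), global average pooling to one value per channel,
then two fully-connected layers (128 and 64 units by default) with dropout
0.5 after each, producing the 64-dim structural embedding.

With the default configuration a 121 x 145 x 121 volume passes through the
spatial chain 121x145x121 -> 60x72x60 -> 30x36x30 -> 15x18x15 -> 7x9x7 with
16/32/64/128 channels; :func:`propagate_shapes` computes that chain without
allocating weights so configurations can be validated up front.  The branch
is size-parameterized: any input large enough for the kernels is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ContractViolationError
from .nn import BatchNorm, Conv3d, Dropout, Linear, MaxPool3d, Param, ReLU
from .types import BranchFeature

__all__ = [
    "CNNBranchConfig",
    "CNNBlock",
    "CNNBranch",
    "conv_block_forward",
    "global_average_pool",
    "cnn_head_forward",
    "propagate_shapes",
]


@dataclass
class CNNBranchConfig:
    """Architecture of the structural branch."""

    conv_channels: list[int] = field(default_factory=lambda: [16, 32, 64, 128])
    kernel_size: int = 3
    pool_size: int = 2
    fc_widths: tuple[int, int] = (128, 64)
    dropout_rate: float = 0.5
    batch_norm: bool = True
    zscore_input: bool = True

    def __post_init__(self) -> None:
        if not self.conv_channels or any(c <= 0 for c in self.conv_channels):
            raise ConfigError("conv channels must be positive and nonempty")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigError("kernel size must be a positive odd integer")
        if self.pool_size != 2:
            raise ConfigError("only 2x2x2 stride-2 pooling is supported")
        if len(self.fc_widths) != 2 or any(w <= 0 for w in self.fc_widths):
            raise ConfigError("fc_widths must be two positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")


def propagate_shapes(
    cfg: CNNBranchConfig, input_shape: tuple[int, int, int]
) -> list[tuple[tuple[int, int, int], int]]:
    """Deterministic shape chain of the conv/pool stages.

    Returns one ``((H, W, D), channels)`` entry per stage, alternating the
    conv output (same spatial size, new channel count) and the pool output
    (floor-halved spatial size).  Raises :class:`ConfigError` if any stage
    collapses to zero size.
    """
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ConfigError(f"input shape must be three positive dims, got {input_shape}")
    chain: list[tuple[tuple[int, int, int], int]] = []
    for i, channels in enumerate(cfg.conv_channels):
        if min(shape) < cfg.kernel_size:
            raise ConfigError(
                f"block {i + 1}: spatial shape {shape} smaller than the "
                f"{cfg.kernel_size}^3 kernel"
            )
        chain.append((shape, channels))  # conv: same-padding preserves size
        shape = tuple(s // cfg.pool_size for s in shape)
        if min(shape) < 1:
            raise ConfigError(
                f"block {i + 1}: pooling collapses spatial shape to {shape}"
            )
        chain.append((shape, channels))
    return chain


class CNNBlock:
    """conv -> (batch norm) -> ReLU -> max-pool."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        batch_norm: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
        name: str = "block",
    ) -> None:
        self.conv = Conv3d(in_channels, out_channels, kernel_size, rng, dtype, name=f"{name}.conv")
        self.bn = BatchNorm(out_channels, dtype=dtype, name=f"{name}.bn") if batch_norm else None
        self.relu = ReLU()
        self.pool = MaxPool3d()

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        x = self.conv.forward(x, mode)
        if self.bn is not None:
            x = self.bn.forward(x, mode)
        x = self.relu.forward(x, mode)
        return self.pool.forward(x, mode)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        grad = self.pool.backward(grad)
        grad = self.relu.backward(grad)
        if self.bn is not None:
            grad = self.bn.backward(grad)
        return self.conv.backward(grad, need_input_grad=need_input_grad)

    def params(self) -> list[Param]:
        out = self.conv.params()
        if self.bn is not None:
            out.extend(self.bn.params())
        return out


def conv_block_forward(v: np.ndarray, block: CNNBlock, mode: str = "eval") -> np.ndarray:
    """Run one subject's (channels, H, W, D) feature map through a block."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 4:
        raise ContractViolationError(
            f"conv block expects a (channels, H, W, D) array, got shape {v.shape}"
        )
    # layers compute channels-last; keep the channels-first subject contract
    out = block.forward(v.transpose(1, 2, 3, 0)[None], mode)[0]
    return out.transpose(3, 0, 1, 2)


def global_average_pool(v: np.ndarray) -> np.ndarray:
    """Per-channel mean over all voxels of a (channels, H, W, D) map."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 4 or min(v.shape[1:]) < 1:
        raise ContractViolationError(
            f"GAP expects a (channels, H, W, D) array with nonempty spatial dims, "
            f"got shape {v.shape}"
        )
    return v.mean(axis=(1, 2, 3))


def cnn_head_forward(
    g_s: np.ndarray, branch: "CNNBranch", mode: str = "eval"
) -> BranchFeature:
    """FC + ReLU + dropout twice, mapping the pooled channel vector to the
    structural embedding."""
    g_s = np.asarray(g_s, dtype=float).ravel()
    out = branch.head_forward(g_s[None, :], mode)
    return BranchFeature(subject_id="", modality="structural", values=out[0])


class CNNBranch:
    """Trainable structural branch operating on batches of volumes.

    ``forward`` takes channels-last (B, H, W, D, 1) volumes and returns the
    (B, fc_widths[1]) embedding matrix.  Input volumes are expected to be
    intensity-normalized upstream (see ``CNNBranchConfig.zscore_input``).
    """

    def __init__(
        self,
        cfg: CNNBranchConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
        in_channels: int = 1,
    ) -> None:
        self.cfg = cfg if cfg is not None else CNNBranchConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        channels = [in_channels] + list(self.cfg.conv_channels)
        self.blocks = [
            CNNBlock(
                channels[i],
                channels[i + 1],
                self.cfg.kernel_size,
                self.cfg.batch_norm,
                rng,
                dtype,
                name=f"cnn.block{i}",
            )
            for i in range(len(self.cfg.conv_channels))
        ]
        w1, w2 = self.cfg.fc_widths
        self.fc1 = Linear(channels[-1], w1, rng, dtype, name="cnn.fc1")
        self.fc2 = Linear(w1, w2, rng, dtype, name="cnn.fc2")
        self.relu1, self.relu2 = ReLU(), ReLU()
        self.drop1 = Dropout(self.cfg.dropout_rate, rng=np.random.default_rng(rng.integers(2**31)))
        self.drop2 = Dropout(self.cfg.dropout_rate, rng=np.random.default_rng(rng.integers(2**31)))

    def head_forward(self, g: np.ndarray, mode: str = "train") -> np.ndarray:
        h = self.drop1.forward(self.relu1.forward(self.fc1.forward(g, mode), mode), mode)
        return self.drop2.forward(self.relu2.forward(self.fc2.forward(h, mode), mode), mode)

    def head_backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(self.drop2.backward(grad))
        grad = self.fc2.backward(grad)
        grad = self.relu1.backward(self.drop1.backward(grad))
        return self.fc1.backward(grad)

    def forward(self, volumes: np.ndarray, mode: str = "train") -> np.ndarray:
        if volumes.ndim != 5:
            raise ContractViolationError(
                f"CNN branch expects (B, H, W, D, C) volumes, got shape {volumes.shape}"
            )
        x = volumes
        for block in self.blocks:
            x = block.forward(x, mode)
        self._gap_shape = x.shape
        g = x.mean(axis=(1, 2, 3))
        return self.head_forward(g, mode)

    def backward(self, grad: np.ndarray) -> None:
        dg = self.head_backward(grad)
        b, h, w, d, c = self._gap_shape
        dx = np.broadcast_to(
            dg[:, None, None, None, :] / (h * w * d), self._gap_shape
        ).astype(dg.dtype)
        for i, block in reversed(list(enumerate(self.blocks))):
            # the input layer's gradient has no consumer
            dx = block.backward(dx, need_input_grad=(i > 0))

    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.blocks:
            out.extend(block.params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out
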